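"""Synthetic strain panels with planted Ty elements and machine-readable truth.

The generator emulates the statistical structure a genome-wide Ty survey
assumes: five LTR-retrotransposon families whose LTRs are mutually dissimilar,
a closely related Ty1/Ty2 pair sharing ~80%-identical coding genes, divergent
Ty1 subfamily variants at controlled TYA identity, Ty1/2 recombination hybrids
(full: Ty2 TYB plus 240-nt Ty2 LTR-U3; short: 60-nt Ty2 TYB tail), element
categories (full / solo-LTR / relic), 5-nt target-site duplications, insertion
bias toward planted tRNA genes, and a panel structure mixing ancestral
insertions (shared across strains at homologous coordinates) with
strain-specific ones.

Every planted feature is recorded as a :class:`TruthRecord`, so detection and
mapping stages can be scored for exact recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .align import reverse_complement
from .genome import GenomeAssembly, GenomeFeature, write_gff3

FAMILIES = ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")
CATEGORIES = ("full", "solo_ltr", "relic", "full_hybrid", "short_hybrid")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
U3_LENGTH = 240  # terminal LTR segment a full hybrid inherits from Ty2
SHORT_HYBRID_TAIL = 60  # TYB tail a short hybrid inherits from Ty2


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def mutate_to_identity(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1 - t) * L) distinct positions."""
    n_sub = int(round((1.0 - target_identity) * len(seq)))
    if n_sub == 0:
        return seq
    if n_sub > len(seq):
        raise ValueError("target identity unreachable for this length")
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for pos in positions:
        cur = arr[pos]
        choices = _BASES[_BASES != cur]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def mutate_at_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-site substitutions at the given probability."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for pos in hit:
        cur = arr[pos]
        choices = _BASES[_BASES != cur]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class TyTemplate:
    """Sequence parts of one Ty family (or subfamily variant)."""

    family: str
    subfamily_label: str
    ltr: str
    tya: str
    tyb: str

    @property
    def u3(self) -> str:
        """Terminal U3 segment of the LTR (last 240 nt)."""
        return self.ltr[-U3_LENGTH:]

    @property
    def full_sequence(self) -> str:
        return self.ltr + self.tya + self.tyb + self.ltr

    def element_sequence(self, category: str) -> str:
        if category in ("full", "full_hybrid", "short_hybrid"):
            return self.full_sequence
        if category == "solo_ltr":
            return self.ltr
        if category == "relic":
            return self.ltr + self.tya
        raise ValueError(f"unknown category {category!r}")


# family -> (ltr, tya, tyb) lengths; LTR sizes straddle the ~330 nt of Ty1
_PART_LENGTHS = {
    "Ty1": (330, 1300, 3600),
    "Ty2": (330, 1300, 3600),
    "Ty3": (340, 1300, 3600),
    "Ty4": (370, 1300, 3600),
    "Ty5": (250, 1300, 3600),
}

# subfamily variants declared with the templates: label -> (parent, region, identity)
DEFAULT_VARIANTS = {
    "Ty1p": ("Ty1", "tya", 0.89),
    "Ty102": ("Ty1", "tya", 0.92),
}

# identity of Ty2 coding genes to Ty1 (closely related, clearly separable)
TY2_CODING_IDENTITY = 0.80


def make_variant(
    parent: TyTemplate, region: str, target_identity: float,
    seed: int, label: str | None = None,
) -> TyTemplate:
    """Derive a subfamily variant by substituting one region of a template."""
    if not (0.5 < target_identity <= 1.0):
        raise ValueError("target_identity must lie in (0.5, 1.0]")
    if region not in ("ltr", "tya", "tyb"):
        raise ValueError(f"unknown region {region!r}")
    if target_identity == 1.0:
        return parent
    rng = np.random.default_rng(seed)
    mutated = mutate_to_identity(getattr(parent, region), target_identity, rng)
    return replace(
        parent,
        subfamily_label=label or f"{parent.family}_{region}{int(round(target_identity * 100))}",
        **{region: mutated},
    )


def make_hybrid(ty1: TyTemplate, ty2: TyTemplate, kind: str) -> TyTemplate:
    """Build a Ty1/2 recombination hybrid template.

    full  -> Ty1 TYA, Ty2 TYB, both LTRs carrying Ty2's terminal 240-nt U3
    short -> pure Ty1 except the last 60 nt of TYB come from Ty2
    """
    if kind == "full":
        return TyTemplate(
            family="Ty1",
            subfamily_label="hybrid_full",
            ltr=ty1.ltr[:-U3_LENGTH] + ty2.u3,
            tya=ty1.tya,
            tyb=ty2.tyb,
        )
    if kind == "short":
        return TyTemplate(
            family="Ty1",
            subfamily_label="hybrid_short",
            ltr=ty1.ltr,
            tya=ty1.tya,
            tyb=ty1.tyb[:-SHORT_HYBRID_TAIL] + ty2.tyb[-SHORT_HYBRID_TAIL:],
        )
    raise ValueError(f"unknown hybrid kind {kind!r}")


def build_templates(seed: int, variants: dict | None = None) -> dict[str, TyTemplate]:
    """Five family templates plus declared subfamily variants, deterministic.

    Family LTRs are mutually unrelated (global identity well below 0.60);
    Ty2's coding genes are derived from Ty1 at ~80% identity so that the two
    families are closely related in coding sequence but separable, as in the
    real Ty1/Ty2 pair.  Hybrid templates are available under the keys
    ``hybrid_full`` and ``hybrid_short``.
    """
    rng = np.random.default_rng(seed)
    templates: dict[str, TyTemplate] = {}
    for family in FAMILIES:
        l_ltr, l_tya, l_tyb = _PART_LENGTHS[family]
        if family == "Ty2":
            ty1 = templates["Ty1"]
            templates[family] = TyTemplate(
                family=family,
                subfamily_label=family,
                ltr=random_sequence(rng, l_ltr),
                tya=mutate_to_identity(ty1.tya, TY2_CODING_IDENTITY, rng),
                tyb=mutate_to_identity(ty1.tyb, TY2_CODING_IDENTITY, rng),
            )
        else:
            templates[family] = TyTemplate(
                family=family,
                subfamily_label=family,
                ltr=random_sequence(rng, l_ltr),
                tya=random_sequence(rng, l_tya),
                tyb=random_sequence(rng, l_tyb),
            )
    for label, (parent, region, identity) in (variants or DEFAULT_VARIANTS).items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        templates[label] = make_variant(
            templates[parent], region, identity, sub_seed, label=label
        )
    templates["hybrid_full"] = make_hybrid(templates["Ty1"], templates["Ty2"], "full")
    templates["hybrid_short"] = make_hybrid(templates["Ty1"], templates["Ty2"], "short")
    return templates


@dataclass
class CategoryCounts:
    full: int = 0
    solo_ltr: int = 0
    relic: int = 0
    full_hybrid: int = 0
    short_hybrid: int = 0

    def total(self) -> int:
        return self.full + self.solo_ltr + self.relic + self.full_hybrid + self.short_hybrid

    def ltr_copies(self) -> int:
        """LTR copies contributed per category (full elements carry two)."""
        return (
            2 * (self.full + self.full_hybrid + self.short_hybrid)
            + self.solo_ltr
            + self.relic
        )


def default_counts() -> dict[str, CategoryCounts]:
    """Per-strain family composition: 54 LTR copies, 59% of them Ty1."""
    return {
        "Ty1": CategoryCounts(full=2, solo_ltr=27, relic=1),
        "Ty2": CategoryCounts(full=1, solo_ltr=9),
        "Ty3": CategoryCounts(full=1, solo_ltr=4),
        "Ty4": CategoryCounts(solo_ltr=3),
        "Ty5": CategoryCounts(solo_ltr=2),
    }


@dataclass
class PlantSpec:
    """Study conditions for a synthetic panel."""

    counts: dict[str, CategoryCounts] = field(default_factory=default_counts)
    variant_full_counts: dict[str, int] = field(default_factory=lambda: {"Ty1p": 1})
    subfamily_identities: dict[str, float] = field(
        default_factory=lambda: {"Ty1p": 0.89, "Ty102": 0.92}
    )
    nesting_prob: float = 0.0
    polIII_bias: float = 0.62
    tsd_length: int = 5
    ancestral_fraction: float = 0.5
    divergence_rate: float = 0.0
    seed: int = 0
    genome_length: int = 1_000_000
    n_strains: int = 8
    trna_per_mb: int = 25
    trna_length: int = 72
    trna_window: tuple[int, int] = (50, 700)  # offset band for biased placement
    min_separation: int = 150  # between planted junctions, panel-wide
    edge_margin: int = 5_000

    def __post_init__(self) -> None:
        for name in ("nesting_prob", "polIII_bias", "ancestral_fraction", "divergence_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for fam, cc in self.counts.items():
            if min(asdict(cc).values()) < 0:
                raise ValueError(f"negative count for {fam}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth annotation of one planted feature."""

    strain: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    subfamily_label: str
    category: str
    locus_id: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class _PlannedInsertion:
    locus_id: str
    contig: str
    position: int  # junction on the background (= reference) coordinates
    strand: str
    family: str
    template_key: str
    category: str
    near_polIII: bool
    ancestral: bool
    nested_in: str | None = None  # host locus_id


def make_background(
    rng: np.random.Generator, length: int, n_trna: int, trna_length: int,
    contig: str = "chr1", edge_margin: int = 5_000, min_gap: int = 2_000,
) -> tuple[GenomeAssembly, list[GenomeFeature]]:
    """Random background with tRNA marker genes substituted in place."""
    seq = random_sequence(rng, length)
    positions: list[int] = []
    tries = 0
    while len(positions) < n_trna and tries < 50 * n_trna:
        tries += 1
        pos = int(rng.integers(edge_margin, length - edge_margin - trna_length))
        if all(abs(pos - p) >= min_gap for p in positions):
            positions.append(pos)
    positions.sort()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    features = []
    for i, pos in enumerate(positions):
        marker = random_sequence(rng, trna_length)
        arr[pos : pos + trna_length] = np.frombuffer(marker.encode("ascii"), np.uint8)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GenomeFeature(contig, pos, pos + trna_length, strand, f"tRNA{i:03d}")
        )
    assembly = GenomeAssembly("reference", {contig: arr.tobytes().decode("ascii")})
    return assembly, features


class _PositionSampler:
    """Draws insertion junctions, optionally tRNA-adjacent, with a panel-wide
    minimum separation so that distinct planted loci stay distinct."""

    def __init__(self, spec: PlantSpec, length: int, trna: list[GenomeFeature]):
        self.spec = spec
        self.length = length
        self.trna = trna
        self.taken: list[int] = []

    def _free(self, pos: int) -> bool:
        return all(abs(pos - p) >= self.spec.min_separation for p in self.taken)

    def draw(self, rng: np.random.Generator) -> tuple[int, bool]:
        spec = self.spec
        lo, hi = spec.trna_window
        want_near = bool(self.trna) and rng.random() < spec.polIII_bias
        if want_near:
            for _ in range(100):
                gene = self.trna[int(rng.integers(len(self.trna)))]
                offset = int(rng.integers(lo, hi))
                pos = gene.end + offset if rng.random() < 0.5 else gene.start - offset
                if spec.edge_margin <= pos <= self.length - spec.edge_margin and self._free(pos):
                    self.taken.append(pos)
                    return pos, True
            # neighborhoods crowded: sweep a deterministic slot grid
            for gene in self.trna:
                for offset in range(lo, hi, max(1, spec.min_separation)):
                    for pos in (gene.end + offset, gene.start - offset):
                        if (
                            spec.edge_margin <= pos <= self.length - spec.edge_margin
                            and self._free(pos)
                        ):
                            self.taken.append(pos)
                            return pos, True
        for _ in range(300):
            pos = int(rng.integers(spec.edge_margin, self.length - spec.edge_margin))
            if self._free(pos):
                self.taken.append(pos)
                return pos, self._near_trna(pos)
        raise RuntimeError(
            "could not place insertion: requested density exceeds the background"
        )

    def _near_trna(self, pos: int) -> bool:
        hi = self.spec.trna_window[1]
        return any(g.start - hi <= pos <= g.end + hi for g in self.trna)


def _expand_template_keys(family: str, category: str, count: int, spec: PlantSpec) -> list[str]:
    """Template key per planted element; Ty1 full elements cycle declared variants."""
    if category in ("full_hybrid", "short_hybrid"):
        key = "hybrid_full" if category == "full_hybrid" else "hybrid_short"
        return [key] * count
    if family == "Ty1" and category == "full":
        keys = []
        variant_budget = dict(spec.variant_full_counts)
        for _ in range(count):
            chosen = "Ty1"
            for label, left in variant_budget.items():
                if left > 0:
                    chosen = label
                    variant_budget[label] = left - 1
                    break
            keys.append(chosen)
        # canonical copies first so every strain keeps a canonical Ty1
        return sorted(keys, key=lambda k: (k != "Ty1", k))
    return [family] * count


def _plan_panel(
    spec: PlantSpec, trna: list[GenomeFeature], length: int,
    rng: np.random.Generator, contig: str,
) -> tuple[list[_PlannedInsertion], list[list[_PlannedInsertion]]]:
    """Shared ancestral insertions plus per-strain specific ones."""
    sampler = _PositionSampler(spec, length, trna)
    ancestral: list[_PlannedInsertion] = []
    strain_specific: list[list[_PlannedInsertion]] = [[] for _ in range(spec.n_strains)]
    anc_idx = 0
    for family in FAMILIES:
        cc = spec.counts.get(family, CategoryCounts())
        for category in CATEGORIES:
            count = getattr(cc, category)
            if count == 0:
                continue
            keys = _expand_template_keys(family, category, count, spec)
            n_anc = int(round(spec.ancestral_fraction * count))
            for i in range(count):
                if i < n_anc:
                    pos, near = sampler.draw(rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    ancestral.append(
                        _PlannedInsertion(
                            f"anc{anc_idx:04d}", contig, pos, strand, family,
                            keys[i], category, near, True,
                        )
                    )
                    anc_idx += 1
                else:
                    for s in range(spec.n_strains):
                        pos, near = sampler.draw(rng)
                        strand = "+" if rng.random() < 0.5 else "-"
                        strain_specific[s].append(
                            _PlannedInsertion(
                                f"s{s}_{len(strain_specific[s]):04d}", contig, pos,
                                strand, family, keys[i], category, near, False,
                            )
                        )
    return ancestral, strain_specific


def _assign_nesting(
    entries: list[_PlannedInsertion], spec: PlantSpec, rng: np.random.Generator
) -> list[_PlannedInsertion]:
    if spec.nesting_prob <= 0.0:
        return entries
    hosts = [e for e in entries if e.category == "full"]
    if not hosts:
        return entries
    out = []
    for e in entries:
        if (
            e.category == "solo_ltr"
            and rng.random() < spec.nesting_prob
        ):
            host = hosts[int(rng.integers(len(hosts)))]
            if host.locus_id != e.locus_id:
                e = replace(e, nested_in=host.locus_id)
        out.append(e)
    return out


def _build_strain(
    strain: str, background: str, contig: str,
    entries: list[_PlannedInsertion], templates: dict[str, TyTemplate],
    spec: PlantSpec, rng: np.random.Generator,
) -> tuple[GenomeAssembly, list[TruthRecord]]:
    tsd = spec.tsd_length
    top = sorted(
        (e for e in entries if e.nested_in is None), key=lambda e: e.position
    )
    nested = [e for e in entries if e.nested_in is not None]
    by_locus = {e.locus_id: e for e in top}

    # element sequence per entry, with per-copy divergence
    seqs: dict[str, str] = {}
    for e in top + nested:
        tpl = templates[e.template_key]
        seqs[e.locus_id] = mutate_at_rate(
            tpl.element_sequence(e.category), spec.divergence_rate, rng
        )

    # splice nested elements into their hosts (middle of the host element)
    nested_offsets: dict[str, tuple[str, int, int]] = {}
    for e in nested:
        host = by_locus.get(e.nested_in)
        if host is None:
            top.append(e)  # host absent in this strain: plant at own position
            top.sort(key=lambda x: x.position)
            continue
        host_seq = seqs[host.locus_id]
        at = len(host_seq) // 2
        ins = seqs[e.locus_id] if e.strand == host.strand else reverse_complement(seqs[e.locus_id])
        seqs[host.locus_id] = host_seq[: at + tsd] + ins + host_seq[at : at + tsd] + host_seq[at + tsd :]
        nested_offsets[e.locus_id] = (host.locus_id, at + tsd, len(ins))

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    added = 0
    starts: dict[str, int] = {}
    for e in top:
        p = e.position
        elem = seqs[e.locus_id]
        if e.strand == "-":
            elem = reverse_complement(elem)
        pieces.append(background[prev : p + tsd])
        start = p + tsd + added
        starts[e.locus_id] = start
        tpl = templates[e.template_key]
        truth.append(
            TruthRecord(
                strain, contig, start, start + len(elem), e.strand,
                e.family, tpl.subfamily_label, e.category, e.locus_id,
            )
        )
        pieces.append(elem)
        added += len(elem) + tsd
        prev = p
    pieces.append(background[prev:])
    seq = "".join(pieces)

    for locus_id, (host_id, rel, ins_len) in nested_offsets.items():
        e = next(x for x in nested if x.locus_id == locus_id)
        host = by_locus[host_id]
        # relative offset holds on the forward strand only for '+' hosts
        if host.strand == "+":
            start = starts[host_id] + rel
        else:
            host_len = len(seqs[host_id])
            start = starts[host_id] + host_len - rel - ins_len
        tpl = templates[e.template_key]
        truth.append(
            TruthRecord(
                strain, contig, start, start + ins_len, e.strand,
                e.family, tpl.subfamily_label, e.category, e.locus_id,
            )
        )
    truth.sort(key=lambda t: t.start)
    return GenomeAssembly(strain, {contig: seq}), truth


def plant_elements(
    background: GenomeAssembly,
    templates: dict[str, TyTemplate],
    spec: PlantSpec,
    trna: list[GenomeFeature] | None = None,
    strain: str = "strain0",
) -> tuple[GenomeAssembly, list[TruthRecord]]:
    """Plant one strain's worth of elements into a background assembly."""
    contig = next(iter(background.contigs))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    one = replace_n_strains(spec, 1)
    ancestral, specific = _plan_panel(one, trna or [], len(background[contig]), rng, contig)
    entries = _assign_nesting(ancestral + specific[0], spec, rng)
    return _build_strain(strain, background[contig], contig, entries, templates, spec, rng)


def replace_n_strains(spec: PlantSpec, n: int) -> PlantSpec:
    import dataclasses

    return dataclasses.replace(spec, n_strains=n)


@dataclass
class SyntheticPanel:
    """A simulated strain panel plus everything needed to score recovery."""

    strains: dict[str, GenomeAssembly]
    truth: list[TruthRecord]
    matrix: pd.DataFrame  # strains x loci boolean occupancy (truth)
    reference: GenomeAssembly
    trna: list[GenomeFeature]
    templates: dict[str, TyTemplate]
    spec: PlantSpec
    loci: pd.DataFrame  # locus_id, family, category, position, near_polIII, ancestral

    def truth_for(self, strain: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.strain == strain]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, asm in self.strains.items():
            asm.to_fasta(outdir / f"{name}.fasta")
        self.reference.to_fasta(outdir / "reference.fasta")
        write_gff3(self.trna, outdir / "trna.gff3")
        with open(outdir / "truth.bed", "w") as fh:
            for t in self.truth:
                name = f"{t.family}:{t.subfamily_label}:{t.category}:{t.locus_id}"
                fh.write(
                    f"{t.contig}\t{t.start}\t{t.end}\t{t.strain}|{name}\t0\t{t.strand}\n"
                )
        self.matrix.astype(int).to_csv(outdir / "truth_matrix.tsv", sep="\t")
        self.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
        payload = asdict(self.spec)
        payload["counts"] = {k: asdict(v) for k, v in self.spec.counts.items()}
        with open(outdir / "plant_spec.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=list)


def simulate_strain_panel(
    spec: PlantSpec,
    templates: dict[str, TyTemplate] | None = None,
    reference: GenomeAssembly | None = None,
    trna: list[GenomeFeature] | None = None,
) -> SyntheticPanel:
    """Simulate ``spec.n_strains`` genomes sharing ancestral insertions.

    A fraction ``ancestral_fraction`` of each strain's insertions comes from
    a shared plan (same background coordinates, same locus_id in every
    strain); the rest are strain-specific.  The returned reference assembly
    is the insertion-free background, which the mapping stage uses as its
    coordinate system.
    """
    if spec.n_strains < 2:
        raise ValueError("a panel needs at least 2 strains")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    templates = templates or build_templates(int(rng.integers(0, 2**31 - 1)))
    if reference is None:
        n_trna = max(8, int(spec.trna_per_mb * spec.genome_length / 1e6))
        reference, trna = make_background(
            rng, spec.genome_length, n_trna, spec.trna_length,
            edge_margin=spec.edge_margin,
        )
    trna = trna or []
    contig = next(iter(reference.contigs))
    background = reference[contig]
    ancestral, specific = _plan_panel(spec, trna, len(background), rng, contig)

    strains: dict[str, GenomeAssembly] = {}
    truth: list[TruthRecord] = []
    strain_names = [f"strain{i:02d}" for i in range(spec.n_strains)]
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_strains + 1)
    for i, name in enumerate(strain_names):
        srng = np.random.default_rng(child_seeds[i + 1])
        entries = _assign_nesting(ancestral + specific[i], spec, srng)
        asm, t = _build_strain(name, background, contig, entries, templates, spec, srng)
        strains[name] = asm
        truth.extend(t)

    locus_rows = []
    seen = set()
    for group in [ancestral] + specific:
        for e in group:
            if e.locus_id in seen:
                continue
            seen.add(e.locus_id)
            locus_rows.append(
                dict(
                    locus_id=e.locus_id, family=e.family, category=e.category,
                    template=e.template_key, position=e.position,
                    strand=e.strand, near_polIII=e.near_polIII,
                    ancestral=e.ancestral,
                )
            )
    loci = pd.DataFrame(locus_rows).sort_values("position").reset_index(drop=True)
    matrix = pd.DataFrame(
        False, index=strain_names, columns=list(loci["locus_id"]), dtype=bool
    )
    for t in truth:
        matrix.loc[t.strain, t.locus_id] = True
    return SyntheticPanel(
        strains=strains, truth=truth, matrix=matrix, reference=reference,
        trna=trna, templates=templates, spec=spec, loci=loci,
    )
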