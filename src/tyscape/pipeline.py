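"""End-to-end orchestration: simulate -> scan -> classify -> atlas -> phylo
-> report, with per-stage artifacts, structured filter counts and a MANIFEST
capturing the configuration of every run."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import phylo as phylo_mod
from .classify import classify_strain, summarize_coding, write_elements_gff3
from .config import PipelineConfig
from .genome import GenomeAssembly, read_gff3_features
from .scan import FAMILIES, QueryPanel, count_by_family, scan_ltrs, write_hits_bed
from .synthetic import build_templates, simulate_strain_panel

log = logging.getLogger("tyscape")

STAGES = ("simulate", "scan", "classify", "atlas", "phylo", "report")


class PipelineRun:
    """In-memory state of one pipeline run plus its on-disk artifacts."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = config.run_dir()
        self.params = config.alignment_params
        self.assemblies: dict[str, GenomeAssembly] = {}
        self.panel: QueryPanel | None = None
        self.reference: GenomeAssembly | None = None
        self.annotation = []
        self.hits = {}
        self.fragments = {}
        self.elements = {}
        self.loci = []
        self.matrices = {}
        self.segments = None
        self.counts: dict[str, dict] = {}
        self.completed: list[str] = []

    # -- inputs ------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        if cfg.simulate is not None:
            panel_obj = simulate_strain_panel(cfg.plant_spec)
            self.assemblies = panel_obj.strains
            self.reference = panel_obj.reference
            self.annotation = panel_obj.trna
            self.panel = QueryPanel.from_templates(panel_obj.templates)
            outdir = self.outdir / "simulate"
            panel_obj.write(outdir)
            self.panel.to_fasta(outdir / "panel.fasta")
            self.truth_panel = panel_obj
            self.counts["simulate"] = {
                "strains": len(self.assemblies),
                "planted_features": len(panel_obj.truth),
                "loci": int(panel_obj.loci.shape[0]),
            }
        else:
            inputs = cfg.inputs or {}
            for path in inputs.get("assemblies", []):
                asm = GenomeAssembly.from_fasta(path)
                self.assemblies[asm.strain] = asm
            self.panel = QueryPanel.from_fasta(inputs["panel"])
            self.reference = GenomeAssembly.from_fasta(inputs["reference"], strain="reference")
            if inputs.get("annotation"):
                self.annotation = read_gff3_features(inputs["annotation"])
            self.truth_panel = None
            self.counts["simulate"] = {"strains": len(self.assemblies)}
        if not self.assemblies:
            raise FileNotFoundError("no input assemblies available")
        self.completed.append("simulate")

    # -- stage 1: LTR census ----------------------------------------------

    def stage_scan(self) -> None:
        outdir = self.outdir / "scan"
        outdir.mkdir(parents=True, exist_ok=True)
        n_hits = 0
        n_frag = 0
        for strain in sorted(self.assemblies):
            hits, frags = scan_ltrs(
                self.assemblies[strain], self.panel, self.params, keep_fragments=True
            )
            self.hits[strain] = hits
            self.fragments[strain] = frags
            n_hits += len(hits)
            n_frag += len(frags)
            log.info("scan: %s -> %d LTR hits (%d sub-threshold)", strain, len(hits), len(frags))
        all_hits = [h for s in sorted(self.hits) for h in self.hits[s]]
        write_hits_bed(all_hits, outdir / "hits.bed")
        all_frags = [h for s in sorted(self.fragments) for h in self.fragments[s]]
        write_hits_bed(all_frags, outdir / "fragments.bed")
        counts = count_by_family(self.hits)
        counts.to_csv(outdir / "ltr_counts.tsv", sep="\t")
        self.counts["scan"] = {"hits": n_hits, "below_min_length": n_frag}
        self.completed.append("scan")

    # -- stage 2: element classification ----------------------------------

    def stage_classify(self) -> None:
        outdir = self.outdir / "classify"
        outdir.mkdir(parents=True, exist_ok=True)
        for strain in sorted(self.assemblies):
            elements = classify_strain(
                self.hits[strain], self.assemblies[strain], self.panel, self.params
            )
            self.elements[strain] = elements
            write_elements_gff3(elements, outdir / f"{strain}.gff3")
        summary = summarize_coding(self.elements)
        summary.to_csv(outdir / "coding_summary.tsv", sep="\t")
        cats = pd.Series(
            [el.category for els in self.elements.values() for el in els]
        ).value_counts()
        self.counts["classify"] = {str(k): int(v) for k, v in sorted(cats.items())}
        self.completed.append("classify")

    # -- stage 3: insertion atlas ------------------------------------------

    def stage_atlas(self) -> None:
        cfg = self.config
        outdir = self.outdir / "atlas"
        outdir.mkdir(parents=True, exist_ok=True)
        mapped = []
        tallies = {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for strain in sorted(self.elements):
            m, tally = atlas_mod.map_elements(
                self.elements[strain], self.assemblies[strain], self.panel,
                self.reference, self.params, cfg.flank_len, cfg.map_margin,
            )
            mapped.extend(m)
            for k, v in tally.items():
                tallies[k] += v
        self.mapped = mapped
        self.loci = atlas_mod.cluster_loci(mapped, cfg.locus_window)
        atlas_mod.write_loci_bed(self.loci, outdir / "loci.bed")
        polIII = atlas_mod.polIII_proximity(self.loci, self.annotation, cfg.polIII_window)
        strains = sorted(self.assemblies)
        spectra = {}
        for family in FAMILIES:
            matrix = atlas_mod.presence_absence_matrix(self.loci, strains, family)
            if matrix.shape[1] == 0:
                continue
            self.matrices[family] = matrix
            matrix.astype(int).to_csv(outdir / f"matrix_{family}.tsv", sep="\t")
            shared = self._shared_with_reference(matrix)
            shared.astype(int).to_csv(outdir / f"shared_ref_{family}.tsv", sep="\t")
            spectra[family] = atlas_mod.occupancy_spectrum(matrix, cfg.spectrum_mode)
            if matrix.shape[0] >= 2:
                newick, strain_order, locus_order = atlas_mod.cluster_strains(matrix)
                (outdir / f"strain_dendrogram_{family}.nwk").write_text(newick + "\n")
                (outdir / f"locus_order_{family}.txt").write_text("\n".join(locus_order) + "\n")
        if spectra:
            pd.DataFrame(spectra).T.to_csv(outdir / "spectra.tsv", sep="\t")
        pd.DataFrame(
            {
                "n_loci": [len(self.loci)],
                "polIII_fraction": [polIII],
            }
        ).to_csv(outdir / "polIII.tsv", sep="\t", index=False)
        self.polIII_fraction = polIII
        self.counts["atlas"] = {**tallies, "loci": len(self.loci)}
        self.completed.append("atlas")

    def _shared_with_reference(self, matrix: pd.DataFrame) -> pd.DataFrame:
        ref = self.config.reference_strain
        shared = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
        if ref and ref in matrix.index:
            ref_row = matrix.loc[ref]
            for col in matrix.columns:
                if ref_row[col]:
                    shared[col] = matrix[col]
        return shared

    # -- stage 4: subfamily phylogeny --------------------------------------

    def stage_phylo(self) -> None:
        cfg = self.config
        outdir = self.outdir / "phylo"
        outdir.mkdir(parents=True, exist_ok=True)
        coding_elements = [
            el
            for strain in sorted(self.elements)
            for el in self.elements[strain]
            if el.family in ("Ty1", "Ty2") and el.category in ("full", "relic")
        ]
        segments = phylo_mod.SegmentSet(segments=[], skipped=[])
        for strain in sorted(self.elements):
            subset = [el for el in self.elements[strain] if el.family in ("Ty1", "Ty2")]
            part = phylo_mod.extract_segments(
                subset, self.assemblies[strain], cfg.segment_len
            )
            segments.segments.extend(part.segments)
            segments.skipped.extend(part.skipped)
        self.segments = segments
        calls = phylo_mod.call_subfamilies(
            segments,
            phylo_mod.exemplars_from_panel(self.panel, "TYA300", cfg.segment_len),
            phylo_mod.exemplars_from_panel(self.panel, "TYB300", cfg.segment_len),
            cfg.subfamily_threshold,
            self.params,
        )
        calls.to_csv(outdir / "subfamilies.tsv", sep="\t", index=False)
        self.subfamily_calls = calls
        n_trees = 0
        for kind in ("TYA300", "TYB300"):
            seqs = segments.of_kind(kind)
            if len(seqs) < 2:
                continue
            aligned = phylo_mod.align_segments(seqs)
            with open(outdir / f"{kind.lower()}_aligned.fasta", "w") as fh:
                for label in sorted(aligned):
                    fh.write(f">{label}\n{aligned[label]}\n")
            labels, dmat = phylo_mod.distance_matrix(aligned)
            pd.DataFrame(dmat, index=labels, columns=labels).to_csv(
                outdir / f"{kind.lower()}_dist.tsv", sep="\t"
            )
            if len(labels) >= 3:
                newick = phylo_mod.nj_tree(labels, dmat)
                (outdir / f"{kind.lower()}_nj.nwk").write_text(newick + "\n")
                n_trees += 1
        self.counts["phylo"] = {
            "segments": len(segments.segments),
            "skipped": len(segments.skipped),
            "trees": n_trees,
            "coding_elements": len(coding_elements),
        }
        self.completed.append("phylo")

    # -- stage 5: report ---------------------------------------------------

    def stage_report(self) -> None:
        outdir = self.outdir / "report"
        outdir.mkdir(parents=True, exist_ok=True)
        # (a) LTR counts with percentages
        counts = count_by_family(self.hits)
        pct = counts[list(FAMILIES)].div(counts["total"].replace(0, pd.NA), axis=0) * 100
        pct = pct.fillna(0.0).round(2).add_suffix("_pct")
        pd.concat([counts, pct], axis=1).to_csv(outdir / "ltr_census.tsv", sep="\t")
        # (b) coding summary + relic list
        summarize_coding(self.elements).to_csv(outdir / "coding_census.tsv", sep="\t")
        relics = [
            dict(strain=el.strain, contig=el.contig, start=el.start, end=el.end,
                 family=el.family, subfamily=el.subfamily_label)
            for strain in sorted(self.elements)
            for el in self.elements[strain]
            if el.category == "relic"
        ]
        pd.DataFrame(relics).to_csv(outdir / "relics.tsv", sep="\t", index=False)
        # (c) occupancy spectra are written by the atlas stage; echo a copy
        spectra_path = self.outdir / "atlas" / "spectra.tsv"
        if spectra_path.exists():
            (outdir / "spectra.tsv").write_text(spectra_path.read_text())
        # (e) subfamily census per strain
        if getattr(self, "subfamily_calls", None) is not None and len(self.subfamily_calls):
            census = (
                self.subfamily_calls[self.subfamily_calls["kind"] == "TYA300"]
                .groupby(["strain", "label"]).size().unstack(fill_value=0)
            )
            census.to_csv(outdir / "subfamily_census.tsv", sep="\t")
        self.counts["report"] = {"tables": len(list(outdir.iterdir()))}
        self.completed.append("report")

    # -- driver ------------------------------------------------------------

    def run(self, stages=STAGES) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        try:
            for stage in stages:
                log.info("stage %s", stage)
                getattr(self, f"stage_{stage}")()
        finally:
            self.write_manifest()
        return self.outdir

    def write_manifest(self) -> None:
        manifest = {
            "config": self.config.to_dict(),
            "stages_completed": self.completed,
            "complete": list(self.completed) == list(STAGES),
            "counts": self.counts,
        }
        with open(self.outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    run = PipelineRun(config)
    return run.run()
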