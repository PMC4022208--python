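"""Genome assemblies and the small amount of file I/O the pipeline needs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GenomeAssembly:
    """A strain's contigs keyed by stable identifiers."""

    strain: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @classmethod
    def from_fasta(cls, path, strain: str | None = None) -> "GenomeAssembly":
        path = Path(path)
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences in {path}")
        return cls(strain=strain or path.stem, contigs=contigs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")  # Biopython wraps at 60 columns


@dataclass(frozen=True)
class GenomeFeature:
    """A located annotation feature (e.g. a Pol III-transcribed gene)."""

    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    feature_id: str
    feature_type: str = "tRNA_gene"


def write_gff3(features, path, source: str = "tyscape") -> None:
    """Write features as GFF3 (coordinates converted to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )


def read_gff3_features(path) -> list[GenomeFeature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            features.append(
                GenomeFeature(
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    feature_id=attrs.get("ID", f"feat{len(features)}"),
                    feature_type=cols[2],
                )
            )
    return features


def read_bed(path) -> list[tuple[str, int, int, str, str, str]]:
    """Read a 6-column BED into (chrom, start, end, name, score, strand) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            score = cols[4] if len(cols) > 4 else "."
            strand = cols[5] if len(cols) > 5 else "+"
            rows.append((chrom, start, end, name, score, strand))
    return rows
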