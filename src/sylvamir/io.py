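"""File-format I/O: FASTA, FASTQ (Phred+33, optional gzip), GFF3, TSV.

FASTA/FASTQ parsing is delegated to Biopython; GFF3 output is a thin writer
for miRNA loci (gene / miRNA_primary_transcript / miRNA feature lines,
1-based closed coordinates per the GFF3 standard).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .qc import ReadRecord


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual) or not seq:
                raise ValueError(f"malformed FASTQ record at index {idx}: {title!r}")
            yield ReadRecord(
                id=title.split()[0],
                sequence=seq.upper(),
                qualities=[ord(c) - 33 for c in qual],
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write ReadRecords as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(loci, path: str | Path) -> None:
    """Write annotated miRNA loci as GFF3.

    One ``miRNA_primary_transcript`` line per locus (the trimmed precursor)
    with child ``miRNA`` lines for the mature and star sequences.
    Coordinates are converted from the internal 0-based half-open convention
    to GFF3 1-based closed.
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            seq_id, start, end, strand = locus.coordinates
            attrs = f"ID={locus.name};status={locus.status}"
            if locus.family:
                attrs += f";family={locus.family}"
            fh.write(
                "\t".join(
                    [
                        seq_id,
                        "sylvamir",
                        "miRNA_primary_transcript",
                        str(start + 1),
                        str(end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for role, subseq in (("mature", locus.mature), ("star", locus.star)):
                sub = locus.arm_coordinates(role)
                if sub is None:
                    continue
                s, e = sub
                fh.write(
                    "\t".join(
                        [
                            seq_id,
                            "sylvamir",
                            "miRNA",
                            str(s + 1),
                            str(e),
                            ".",
                            strand,
                            ".",
                            f"ID={locus.name}-{role};Parent={locus.name};seq={subseq}",
                        ]
                    )
                    + "\n"
                )


def read_gff3_loci(path: str | Path) -> list[dict]:
    """Parse the locus lines written by :func:`write_gff3` back to dicts."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            out.append(
                {
                    "seq_id": fields[0],
                    "type": fields[2],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "attributes": attrs,
                }
            )
    return out


# ---------------------------------------------------------------------------
# TSV term maps
# ---------------------------------------------------------------------------

def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> ``{term: {genes}}``."""
    terms: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            terms.setdefault(term, set()).add(gene)
    return terms


def write_term_map(terms: dict[str, set[str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")
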