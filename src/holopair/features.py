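"""Genome-level sequence features: length and GC content.

Gene counts are carried through from upstream gene calling and are never
computed here. GC content is computed over unambiguous bases only
(A/C/G/T); ambiguous IUPAC codes count toward genome length but not
toward the GC denominator.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import InputError

IUPAC_NUCLEOTIDES = set("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class GenomeFeatures:
    genome_id: str
    length_bp: int
    gc_percent: float  # NaN when the genome has no unambiguous base
    gene_count: int | None = None


def _gc_counts(sequence: str) -> tuple[int, int]:
    """(#G+#C, #A+#C+#G+#T) with IUPAC validation, case-insensitive."""
    s = sequence.upper()
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        raise InputError(f"non-IUPAC nucleotide character(s): {', '.join(sorted(bad))}")
    gc = s.count("G") + s.count("C")
    atgc = gc + s.count("A") + s.count("T")
    return gc, atgc


def gc_content(sequence: str) -> float:
    """Percent GC over unambiguous bases; NaN if there are none.

    ``gc = 100 * (#G + #C) / (#A + #C + #G + #T)``, case-insensitive.
    Raises :class:`InputError` on characters outside the IUPAC alphabet.
    """
    gc, atgc = _gc_counts(sequence)
    if atgc == 0:
        return math.nan
    return 100.0 * gc / atgc


def genome_features_from_fasta(path: str | Path, genome_id: str | None = None) -> GenomeFeatures:
    """Pooled length and GC over all contigs of a (optionally gzipped) FASTA.

    Length includes ambiguous bases; GC pools G+C and A+C+G+T counts over
    contigs, so it equals the length-weighted average of per-contig GC.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    total_len = 0
    total_gc = 0
    total_atgc = 0
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq)
            total_len += len(seq)
            gc, atgc = _gc_counts(seq)
            total_gc += gc
            total_atgc += atgc
    if total_len == 0:
        raise InputError(f"{path}: empty FASTA")
    gc_pct = 100.0 * total_gc / total_atgc if total_atgc else math.nan
    if genome_id is None:
        genome_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    return GenomeFeatures(genome_id=genome_id, length_bp=total_len, gc_percent=gc_pct)


def features_table(fasta_dir: str | Path, pattern: str = "*.fasta"):
    """GenomeFeatures for every FASTA in a directory, as a DataFrame."""
    import pandas as pd

    rows = []
    for path in sorted(Path(fasta_dir).glob(pattern)) + sorted(Path(fasta_dir).glob(pattern + ".gz")):
        f = genome_features_from_fasta(path)
        rows.append({"genome_id": f.genome_id, "length_bp": f.length_bp, "gc_percent": f.gc_percent})
    return pd.DataFrame(rows, columns=["genome_id", "length_bp", "gc_percent"])
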