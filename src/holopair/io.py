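"""Readers, writers and validators for the paired-genome data model.

All tabular formats are UTF-8, tab-separated, with a mandatory header row,
matching the supplementary-table idiom of comparative-genomics studies.
Lines starting with ``#`` are treated as comments (the pipeline writes a
provenance header into every output table).

The central design constraint is the *paired* structure of the study:
every ``pair_id`` joins exactly one host-associated genome with one
free-living genome of the same genus. Every statistic downstream of this
module assumes that invariant, so it is enforced at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    FormatError,
    PairingError,
    UnknownGenomeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LIFESTYLES = ("host", "free")
SOURCES = ("WGS", "MAG")

METADATA_COLUMNS = (
    "genome_id",
    "genus",
    "taxon_class",
    "lifestyle",
    "pair_id",
    "source",
)
OPTIONAL_METADATA_COLUMNS = ("completeness", "redundancy", "host_species")


@dataclass(frozen=True)
class GenomeMeta:
    """One genome of the paired collection.

    ``completeness`` and ``redundancy`` are single-copy-gene quality
    percentages and are only meaningful for MAGs; WGS records leave them
    ``None``.
    """

    genome_id: str
    genus: str
    taxon_class: str
    lifestyle: str  # "host" | "free"
    pair_id: str
    source: str  # "WGS" | "MAG"
    completeness: float | None = None
    redundancy: float | None = None
    host_species: str | None = None


@dataclass(frozen=True)
class ModuleDefinition:
    """A metabolic module as an ordered series of enzymatic steps.

    Each step is a nonempty set of alternative KO identifiers; a genome
    satisfies a step if it carries at least one of the alternatives.
    """

    module_id: str
    name: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise FormatError(f"module {self.module_id}: at least one step required")
        if any(len(s) == 0 for s in self.steps):
            raise FormatError(f"module {self.module_id}: empty step not allowed")


# ---------------------------------------------------------------------------
# genome metadata
# ---------------------------------------------------------------------------


def _records_from_frame(df: pd.DataFrame) -> list[GenomeMeta]:
    records = []
    for row in df.itertuples(index=False):
        lifestyle = str(row.lifestyle)
        if lifestyle not in LIFESTYLES:
            raise FormatError(
                f"genome {row.genome_id}: lifestyle {lifestyle!r} not allowed; "
                f"allowed values are {', '.join(LIFESTYLES)}"
            )
        source = str(row.source)
        if source not in SOURCES:
            raise FormatError(
                f"genome {row.genome_id}: source {source!r} not allowed; "
                f"allowed values are {', '.join(SOURCES)}"
            )

        def _opt_float(name: str) -> float | None:
            val = getattr(row, name, None)
            if val is None or pd.isna(val):
                return None
            val = float(val)
            if not 0.0 <= val <= 100.0:
                raise ValidationError(
                    f"genome {row.genome_id}: {name}={val} outside [0, 100]"
                )
            return val

        def _opt_str(name: str) -> str | None:
            val = getattr(row, name, None)
            if val is None or pd.isna(val):
                return None
            return str(val)

        records.append(
            GenomeMeta(
                genome_id=str(row.genome_id),
                genus=str(row.genus),
                taxon_class=str(row.taxon_class),
                lifestyle=lifestyle,
                pair_id=str(row.pair_id),
                source=source,
                completeness=_opt_float("completeness"),
                redundancy=_opt_float("redundancy"),
                host_species=_opt_str("host_species"),
            )
        )
    return records


def validate_pairing(records: Sequence[GenomeMeta]) -> None:
    """Check the paired-design invariants, raising :class:`PairingError`.

    Every ``pair_id`` must map to exactly one host-associated and one
    free-living genome, and both members must share the same genus.
    """
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise PairingError(f"duplicate genome ids: {', '.join(dupes)}")
    by_pair: dict[str, list[GenomeMeta]] = {}
    for r in records:
        by_pair.setdefault(r.pair_id, []).append(r)
    for pair_id, members in by_pair.items():
        lifestyles = sorted(m.lifestyle for m in members)
        if lifestyles != ["free", "host"]:
            raise PairingError(
                f"pair {pair_id}: expected exactly one host and one free genome, "
                f"got lifestyles {lifestyles}"
            )
        genera = {m.genus for m in members}
        if len(genera) != 1:
            raise PairingError(
                f"pair {pair_id}: genus mismatch within pair ({', '.join(sorted(genera))})"
            )


def read_genome_metadata(path: str | Path) -> list[GenomeMeta]:
    """Read and validate the genome metadata table.

    Raises :class:`FormatError` for a missing column or a bad enum value,
    :class:`PairingError` if the paired design is violated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("completeness", "redundancy"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    records = _records_from_frame(df)
    validate_pairing(records)
    return records


def write_genome_metadata(records: Sequence[GenomeMeta], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[GenomeMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed like the input order."""
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "genus": r.genus,
                "taxon_class": r.taxon_class,
                "lifestyle": r.lifestyle,
                "pair_id": r.pair_id,
                "source": r.source,
                "completeness": r.completeness,
                "redundancy": r.redundancy,
                "host_species": r.host_species,
            }
            for r in records
        ]
    )


def filter_mag_quality(
    records: Sequence[GenomeMeta],
    min_completeness: float = 50.0,
    max_redundancy: float = 10.0,
    drop_broken_pairs: bool = True,
) -> list[GenomeMeta]:
    """Apply the MAG quality filter; WGS records bypass it.

    A MAG is kept iff ``completeness >= min_completeness`` and
    ``redundancy <= max_redundancy`` (boundary values pass). Because every
    downstream statistic is pair-based, removing one member of a pair
    drops the whole pair (logged); pass ``drop_broken_pairs=False`` to
    keep orphans and let :func:`validate_pairing` fail instead.
    """
    kept: list[GenomeMeta] = []
    for r in records:
        if r.source == "WGS":
            kept.append(r)
            continue
        if r.completeness is None or r.redundancy is None:
            raise ValidationError(
                f"MAG {r.genome_id}: completeness/redundancy required for quality filter"
            )
        if r.completeness >= min_completeness and r.redundancy <= max_redundancy:
            kept.append(r)
    if drop_broken_pairs:
        counts: dict[str, int] = {}
        for r in kept:
            counts[r.pair_id] = counts.get(r.pair_id, 0) + 1
        broken = {p for p, n in counts.items() if n != 2}
        # pairs that lost both members are already gone; log orphaned ones
        orphaned = [r.genome_id for r in kept if r.pair_id in broken]
        if orphaned:
            logger.warning(
                "MAG filter broke %d pair(s); dropping orphaned genome(s): %s",
                len(broken),
                ", ".join(orphaned),
            )
        kept = [r for r in kept if r.pair_id not in broken]
    return kept


# ---------------------------------------------------------------------------
# KO presence/absence matrix
# ---------------------------------------------------------------------------


def read_ko_table(path: str | Path, metadata: Sequence[GenomeMeta]) -> pd.DataFrame:
    """Read a KO annotation table into a binary genomes x KOs matrix.

    Two dialects are auto-detected from the header: a long format with
    columns ``genome_id`` and ``ko_id`` (one row per annotation), and a
    wide 0/1 matrix whose first column is ``genome_id``. Duplicate long
    rows collapse to a single presence; nonzero wide values are coerced
    to 1 with a warning. The result is aligned to the metadata genome
    order, with unannotated genomes as all-zero rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    genome_order = [r.genome_id for r in metadata]
    known = set(genome_order)
    if list(df.columns[:2]) == ["genome_id", "ko_id"] and df.shape[1] == 2:
        df["genome_id"] = df["genome_id"].astype(str)
        df["ko_id"] = df["ko_id"].astype(str)
        unknown = sorted(set(df["genome_id"]) - known)
        if unknown:
            raise UnknownGenomeError(
                f"{path}: genome id(s) not in metadata: {', '.join(unknown)}"
            )
        wide = (
            df.assign(present=1)
            .pivot_table(index="genome_id", columns="ko_id", values="present", aggfunc="max")
            .fillna(0)
        )
    elif df.columns[0] == "genome_id":
        df["genome_id"] = df["genome_id"].astype(str)
        unknown = sorted(set(df["genome_id"]) - known)
        if unknown:
            raise UnknownGenomeError(
                f"{path}: genome id(s) not in metadata: {', '.join(unknown)}"
            )
        wide = df.set_index("genome_id")
        values = wide.to_numpy()
        if ((values != 0) & (values != 1)).any():
            logger.warning("%s: nonzero values coerced to presence (1)", path)
        wide = (wide != 0).astype("int8")
    else:
        raise FormatError(
            f"{path}: cannot detect dialect; expected long (genome_id, ko_id) "
            "or wide matrix with leading genome_id column"
        )
    wide = wide.reindex(index=genome_order, columns=sorted(wide.columns), fill_value=0)
    wide.index.name = "genome_id"
    wide.columns.name = "ko_id"
    return wide.astype("int8")


def write_ko_table(ko: pd.DataFrame, path: str | Path) -> None:
    """Write the wide 0/1 KO matrix."""
    ko.to_csv(path, sep="\t", index=True, index_label="genome_id")


# ---------------------------------------------------------------------------
# module definitions
# ---------------------------------------------------------------------------


def parse_module_definition(module_id: str, definition: str, name: str = "") -> ModuleDefinition:
    """Parse the step grammar: steps separated by ';', alternatives by ','."""
    steps = []
    for step_token in definition.split(";"):
        kos = frozenset(k.strip() for k in step_token.split(",") if k.strip())
        if not kos:
            raise FormatError(
                f"module {module_id}: empty step in definition {definition!r}"
            )
        steps.append(kos)
    if not steps:
        raise FormatError(f"module {module_id}: empty definition")
    return ModuleDefinition(module_id=module_id, name=name, steps=tuple(steps))


def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    """Read the module-definition table (columns module_id, definition[, name])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "module_id" not in df.columns or "definition" not in df.columns:
        raise FormatError(f"{path}: required columns are module_id and definition")
    names = (
        df["name"].fillna("").astype(str).tolist()
        if "name" in df.columns
        else [""] * len(df)
    )
    return [
        parse_module_definition(str(mid), str(definition), name)
        for mid, definition, name in zip(df["module_id"], df["definition"], names)
    ]


def write_module_definitions(modules: Iterable[ModuleDefinition], path: str | Path) -> None:
    rows = [
        {
            "module_id": m.module_id,
            "definition": ";".join(",".join(sorted(step)) for step in m.steps),
            "name": m.name,
        }
        for m in modules
    ]
    pd.DataFrame(rows, columns=["module_id", "definition", "name"]).to_csv(
        path, sep="\t", index=False
    )
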