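"""Per-KO paired odds ratios with within-genus re-pairing permutations.

For each KO the odds ratio is built from *discordant* genome pairs only:

    OR = (n_host_only + 0.5) / (n_free_only + 0.5)

where ``n_host_only`` counts pairs carrying the KO in the host-associated
member only, ``n_free_only`` in the free-living member only, and the 0.5
offset prevents division by zero. Because the assignment of host to free
genomes within a genus is arbitrary when a genus contributes several
genomes per lifestyle, the pairing is redrawn uniformly at random within
each genus (default 100 times) and the median OR over re-pairings is
retained. KOs whose median OR falls at or beyond the upper/lower
percentile of all retained medians (default 95th/5th; 99th/1st for
class-restricted runs) are classified as host- or free-enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, InputError, UnknownGenomeError
from .io import GenomeMeta

logger = logging.getLogger(__name__)

TAIL_HOST = "host_enriched"
TAIL_FREE = "free_enriched"
TAIL_NONE = "none"


@dataclass(frozen=True)
class Pairing:
    """An explicit host-to-free genome matching, one tuple per pair."""

    pairs: tuple[tuple[str, str], ...]  # (host_genome_id, free_genome_id)

    def __len__(self) -> int:
        return len(self.pairs)


def canonical_pairing(metadata: Sequence[GenomeMeta]) -> Pairing:
    """The pairing given by the metadata ``pair_id`` column."""
    by_pair: dict[str, dict[str, str]] = {}
    for r in metadata:
        by_pair.setdefault(r.pair_id, {})[r.lifestyle] = r.genome_id
    pairs = []
    for pair_id in sorted(by_pair):
        members = by_pair[pair_id]
        if set(members) != {"host", "free"}:
            raise DesignError(f"pair {pair_id} is not a host/free pair")
        pairs.append((members["host"], members["free"]))
    return Pairing(pairs=tuple(pairs))


def _pair_indices(ko: pd.DataFrame, pairing: Pairing) -> tuple[np.ndarray, np.ndarray]:
    pos = {g: i for i, g in enumerate(ko.index)}
    try:
        host_idx = np.array([pos[h] for h, _ in pairing.pairs], dtype=int)
        free_idx = np.array([pos[f] for _, f in pairing.pairs], dtype=int)
    except KeyError as exc:
        raise UnknownGenomeError(f"pairing references unknown genome {exc.args[0]!r}") from exc
    return host_idx, free_idx


def _discordant_all(ko_values: np.ndarray, host_idx: np.ndarray, free_idx: np.ndarray):
    """Vectorised (n_host_only, n_free_only) for every KO column."""
    host = ko_values[host_idx]
    free = ko_values[free_idx]
    n_host_only = (host & ~free).sum(axis=0)
    n_free_only = (~host & free).sum(axis=0)
    return n_host_only, n_free_only


def discordant_counts(ko: pd.DataFrame, pairing: Pairing, ko_id: str) -> tuple[int, int]:
    """(n_host_only, n_free_only) discordant-pair counts for one KO."""
    if ko_id not in ko.columns:
        raise UnknownGenomeError(f"KO {ko_id!r} not in matrix")
    host_idx, free_idx = _pair_indices(ko, pairing)
    col = ko.columns.get_loc(ko_id)
    a, b = _discordant_all(ko.to_numpy(dtype=bool)[:, [col]], host_idx, free_idx)
    return int(a[0]), int(b[0])


def odds_ratio(n_host_only: int, n_free_only: int, offset: float = 0.5) -> float:
    """Discordant-pair odds ratio with an additive offset on both counts."""
    if n_host_only < 0 or n_free_only < 0:
        raise InputError("discordant counts must be nonnegative")
    return (n_host_only + offset) / (n_free_only + offset)


def random_repairing(
    metadata: Sequence[GenomeMeta], seed: int | np.random.Generator
) -> Pairing:
    """A uniform-random within-genus bijection of host to free genomes.

    Requires a balanced design (equal host and free counts in every
    genus). Deterministic given an integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_genus: dict[str, dict[str, list[str]]] = {}
    for r in metadata:
        by_genus.setdefault(r.genus, {"host": [], "free": []})[r.lifestyle].append(r.genome_id)
    pairs: list[tuple[str, str]] = []
    for genus in sorted(by_genus):
        hosts = sorted(by_genus[genus]["host"])
        frees = sorted(by_genus[genus]["free"])
        if len(hosts) != len(frees):
            raise DesignError(
                f"genus {genus}: {len(hosts)} host vs {len(frees)} free genomes "
                "(balanced design required for re-pairing)"
            )
        perm = rng.permutation(len(frees))
        pairs.extend((h, frees[j]) for h, j in zip(hosts, perm))
    return Pairing(pairs=tuple(pairs))


def median_or_over_repairings(
    ko: pd.DataFrame,
    metadata: Sequence[GenomeMeta],
    n_rep: int = 100,
    offset: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """ORTable: per-KO median odds ratio over within-genus re-pairings.

    The reported discordant counts are those of the canonical (pair_id)
    pairing; ``median_or`` is the median over ``n_rep`` random
    re-pairings (midpoint convention for even ``n_rep``). One master seed
    spawns a substream per replicate, so results do not depend on the KO
    iteration order. KOs never observed in any genome are dropped with a
    logged count before any percentile computation downstream.
    """
    if n_rep < 1:
        raise InputError("n_rep must be >= 1")
    observed = ko.columns[ko.to_numpy().any(axis=0)]
    n_dropped = ko.shape[1] - len(observed)
    if n_dropped:
        logger.info("dropping %d KO(s) never observed in any genome", n_dropped)
    ko = ko[observed]
    values = ko.to_numpy(dtype=bool)

    host_idx0, free_idx0 = _pair_indices(ko, canonical_pairing(metadata))
    a0, b0 = _discordant_all(values, host_idx0, free_idx0)

    streams = np.random.SeedSequence(seed).spawn(n_rep)
    ors = np.empty((n_rep, len(observed)))
    for rep, stream in enumerate(streams):
        pairing = random_repairing(metadata, np.random.default_rng(stream))
        h_idx, f_idx = _pair_indices(ko, pairing)
        a, b = _discordant_all(values, h_idx, f_idx)
        ors[rep] = (a + offset) / (b + offset)
    median = np.median(ors, axis=0)

    table = pd.DataFrame(
        {
            "n_host_only": a0.astype(int),
            "n_free_only": b0.astype(int),
            "median_or": median,
            "tail": TAIL_NONE,
        },
        index=pd.Index(observed, name="ko_id"),
    )
    return table


def classify_tails(
    table: pd.DataFrame, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> pd.DataFrame:
    """Flag KOs in the extreme tails of the median-OR distribution.

    Thresholds use the nearest-rank (inclusive-boundary) convention:
    host-enriched iff ``median_or >=`` the upper percentile, free-enriched
    iff ``<=`` the lower percentile, both computed over all retained KOs.
    The neutral mass at OR == 1 (often large: concordant-only KOs) is
    never assigned to a tail whose threshold sits exactly at 1, which
    keeps the classification meaningful when that mass spans a
    percentile. Class-restricted runs (e.g. one bacterial class at 1/99)
    use this same operation on the subset table.
    """
    if table.empty:
        raise InputError("empty OR table")
    if not (0.0 < lower_pct < upper_pct < 100.0):
        raise InputError("require 0 < lower_pct < upper_pct < 100")
    ors = table["median_or"].to_numpy()
    upper = np.quantile(ors, upper_pct / 100.0, method="higher")
    lower = np.quantile(ors, lower_pct / 100.0, method="lower")
    is_host = (ors >= upper) & ~((ors == 1.0) & (upper == 1.0))
    is_free = (ors <= lower) & ~((ors == 1.0) & (lower == 1.0))
    both = is_host & is_free  # only possible when ties collapse the thresholds
    is_host &= ~both
    is_free &= ~both
    out = table.copy()
    out["tail"] = np.where(is_host, TAIL_HOST, np.where(is_free, TAIL_FREE, TAIL_NONE))
    return out


def write_or_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="ko_id")
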