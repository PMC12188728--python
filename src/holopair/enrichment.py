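"""Pair-respecting module enrichment: exact sign tests + BH correction.

For each module, the completeness fractions of the two members of every
genome pair are compared; ties are excluded (classical sign test) and the
two-sided exact binomial p-value is computed for the number of
host-greater pairs among the non-tied pairs at p = 0.5. Benjamini-
Hochberg correction is applied across modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import GenomeMeta
from .modules import CompletenessMatrix
from .paired_or import canonical_pairing

DIRECTION_HOST = "host"
DIRECTION_FREE = "free"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    n_host_greater: int
    n_free_greater: int
    n_ties: int
    p_value: float  # NaN when every pair is tied
    direction: str
    q_value: float = math.nan


def sign_test_p(n_greater: int, n_trials: int) -> float:
    """Two-sided exact binomial p at p=0.5: double the smaller tail, cap at 1."""
    if n_trials == 0:
        return math.nan
    lower = stats.binom.cdf(n_greater, n_trials, 0.5)
    upper = stats.binom.sf(n_greater - 1, n_trials, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def paired_sign_binomial(
    host_values: Sequence[float],
    free_values: Sequence[float],
    module_id: str = "",
) -> EnrichmentResult:
    """Sign test on per-pair completeness differences (ties excluded)."""
    host = np.asarray(host_values, dtype=float)
    free = np.asarray(free_values, dtype=float)
    if host.shape != free.shape:
        raise InputError("host and free vectors must have equal length")
    n_host = int((host > free).sum())
    n_free = int((host < free).sum())
    n_ties = int(host.size - n_host - n_free)
    p = sign_test_p(n_host, n_host + n_free)
    if n_host > n_free:
        direction = DIRECTION_HOST
    elif n_free > n_host:
        direction = DIRECTION_FREE
    else:
        direction = DIRECTION_NONE
    return EnrichmentResult(
        module_id=module_id,
        n_host_greater=n_host,
        n_free_greater=n_free,
        n_ties=n_ties,
        p_value=p,
        direction=direction,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input.

    NaN entries (undefined tests) are ignored for the correction and stay
    NaN in the output.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    q = np.full_like(p, math.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def module_enrichment(
    cm: CompletenessMatrix,
    metadata: Sequence[GenomeMeta],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module paired sign tests with BH correction across modules.

    Pairs follow the metadata ``pair_id`` assignments. Returns a table
    with counts, p, q, the direction of the majority of untied pairs, and
    a ``significant`` flag at ``q < alpha``.
    """
    pairing = canonical_pairing(metadata)
    host_ids = [h for h, _ in pairing.pairs]
    free_ids = [f for _, f in pairing.pairs]
    host = cm.df.loc[host_ids]
    free = cm.df.loc[free_ids]
    results = [
        paired_sign_binomial(host[m].to_numpy(), free[m].to_numpy(), module_id=m)
        for m in cm.df.columns
    ]
    table = pd.DataFrame(
        {
            "n_host_greater": [r.n_host_greater for r in results],
            "n_free_greater": [r.n_free_greater for r in results],
            "n_ties": [r.n_ties for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        },
        index=pd.Index([r.module_id for r in results], name="module_id"),
    )
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < alpha
    return table
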