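"""KEGG-module completeness scoring.

A module is an ordered series of steps, each satisfiable by alternative
KOs (OR within a step, AND across steps). Completeness of a module in a
genome is the fraction of steps with at least one alternative present;
the module is called *present* when completeness reaches the threshold
(default 0.75, i.e. at least 75% of the required steps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np
import pandas as pd

from .errors import DegenerateOutputError, InputError
from .io import ModuleDefinition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompletenessMatrix:
    """Genomes x modules completeness fractions plus the presence threshold."""

    df: pd.DataFrame  # float in [0, 1], index genome_id, columns module_id
    threshold: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise InputError(f"presence threshold {self.threshold} outside (0, 1]")

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence calls at the stored threshold."""
        return self.df >= self.threshold


def module_completeness(ko_set: Set[str], module: ModuleDefinition) -> float:
    """Fraction of the module's steps with at least one alternative KO present."""
    satisfied = sum(1 for step in module.steps if not ko_set.isdisjoint(step))
    return satisfied / len(module.steps)


def completeness_matrix(
    ko: pd.DataFrame,
    modules: Sequence[ModuleDefinition],
    threshold: float = 0.75,
) -> CompletenessMatrix:
    """Completeness of every module in every genome.

    ``ko`` is the binary genomes x KOs matrix; KOs a module requires but
    that were never observed contribute unsatisfied steps (a module whose
    KOs are all unobserved scores 0 everywhere, with a warning).
    """
    ko_index = {k: i for i, k in enumerate(ko.columns)}
    values = ko.to_numpy(dtype=bool)
    n_genomes = values.shape[0]
    cols = {}
    for module in modules:
        step_hits = np.zeros((n_genomes, len(module.steps)), dtype=bool)
        any_known = False
        for j, step in enumerate(module.steps):
            idx = [ko_index[k] for k in step if k in ko_index]
            if idx:
                any_known = True
                step_hits[:, j] = values[:, idx].any(axis=1)
        if not any_known:
            logger.warning(
                "module %s references no KO observed in any genome", module.module_id
            )
        cols[module.module_id] = step_hits.mean(axis=1)
    df = pd.DataFrame(cols, index=ko.index)
    df.index.name = "genome_id"
    df.columns.name = "module_id"
    return CompletenessMatrix(df=df, threshold=threshold)


def filter_zero_variance(cm: CompletenessMatrix) -> CompletenessMatrix:
    """Drop modules whose completeness is identical across all genomes.

    Modules always present (or always absent, or constant at any value)
    carry no contrast and are removed before ordination. Raises
    :class:`DegenerateOutputError` if nothing remains.
    """
    variable = cm.df.columns[cm.df.nunique(axis=0) > 1]
    if len(variable) == 0:
        raise DegenerateOutputError("zero-variance filter removed every module")
    return CompletenessMatrix(df=cm.df[variable], threshold=cm.threshold)


def write_completeness(cm: CompletenessMatrix, path) -> None:
    cm.df.to_csv(path, sep="\t", index_label="genome_id")


def read_completeness(path, threshold: float = 0.75) -> CompletenessMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="genome_id")
    return CompletenessMatrix(df=df, threshold=threshold)
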