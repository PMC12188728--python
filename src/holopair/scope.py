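"""Metabolic-network expansion: scopes and host-bacterium "added value".

The *scope* of an organism on a growth medium is the set of metabolites
reachable from the seed (medium) compounds by iteratively firing
reactions whose substrates are all already available — the qualitative
network-expansion semantics (no stoichiometry, no flux). Reversible
reactions are split into two directed reactions before the fixed point.

The *added value* of a host-bacterium cooperation is the set of
compounds producible by the merged network but by neither network alone
— a qualitative measure of metabolic complementarity. Group comparisons
of added values use exact binomial tests per compound with BH correction
and a two-way ANOVA (class x lifestyle, type-II sums of squares) on
per-organism added-value counts, with Tukey HSD post hoc for class.
"""

from __future__ import annotations

import logging
import warnings
import xml.etree.ElementTree as ET
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_adjust, sign_test_p
from .errors import DesignError, FormatError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise FormatError(
                f"reaction {self.reaction_id}: substrate and product sets must be nonempty"
            )


@dataclass(frozen=True)
class ReactionNetwork:
    organism_id: str
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise FormatError(f"network {self.organism_id}: duplicate reaction ids")


@dataclass(frozen=True)
class SeedSet:
    """Growth-medium composition."""

    compounds: frozenset[str]

    def __post_init__(self) -> None:
        if not self.compounds:
            raise InputError("seed set must be nonempty")


@dataclass(frozen=True)
class ScopeResult:
    organism_ids: tuple[str, ...]
    scope: frozenset[str]
    added_value: frozenset[str] | None = None


def _directed(reactions: Iterable[Reaction]) -> list[tuple[frozenset[str], frozenset[str]]]:
    out = []
    for r in reactions:
        out.append((r.substrates, r.products))
        if r.reversible:
            out.append((r.products, r.substrates))
    return out


def expand_scope(network: ReactionNetwork, seeds: SeedSet) -> frozenset[str]:
    """Least fixed point of network expansion from the seed compounds.

    Worklist algorithm: each newly reachable compound notifies the
    reactions consuming it, and a reaction fires once all its substrates
    are available, adding its products. Seeds are always included in the
    scope.
    """
    directed = _directed(network.reactions)
    by_substrate: dict[str, list[int]] = defaultdict(list)
    for i, (subs, _) in enumerate(directed):
        for c in subs:
            by_substrate[c].append(i)
    reachable = set(seeds.compounds)
    queue = list(reachable)
    fired = [False] * len(directed)

    def fire(i: int) -> None:
        fired[i] = True
        for p in directed[i][1]:
            if p not in reachable:
                reachable.add(p)
                queue.append(p)

    for i, (subs, _) in enumerate(directed):
        if not fired[i] and subs <= reachable:
            fire(i)
    while queue:
        compound = queue.pop()
        for i in by_substrate[compound]:
            if not fired[i] and directed[i][0] <= reachable:
                fire(i)
    return frozenset(reachable)


def merge_networks(host: ReactionNetwork, bacterium: ReactionNetwork) -> ReactionNetwork:
    """Union of the two reaction sets (ids kept distinct per side)."""
    reactions = [
        Reaction(f"h::{r.reaction_id}", r.substrates, r.products, r.reversible)
        for r in host.reactions
    ] + [
        Reaction(f"b::{r.reaction_id}", r.substrates, r.products, r.reversible)
        for r in bacterium.reactions
    ]
    return ReactionNetwork(
        organism_id=f"{host.organism_id}+{bacterium.organism_id}", reactions=tuple(reactions)
    )


def added_value(
    host: ReactionNetwork, bacterium: ReactionNetwork, seeds: SeedSet
) -> frozenset[str]:
    """Compounds producible by the merged network but by neither alone."""
    merged_scope = expand_scope(merge_networks(host, bacterium), seeds)
    host_scope = expand_scope(host, seeds)
    bact_scope = expand_scope(bacterium, seeds)
    return merged_scope - (host_scope | bact_scope)


def cooperation_scope(
    host: ReactionNetwork, bacterium: ReactionNetwork, seeds: SeedSet
) -> ScopeResult:
    """Merged-network scope together with the cooperation's added value."""
    merged_scope = expand_scope(merge_networks(host, bacterium), seeds)
    host_scope = expand_scope(host, seeds)
    bact_scope = expand_scope(bacterium, seeds)
    return ScopeResult(
        organism_ids=(host.organism_id, bacterium.organism_id),
        scope=merged_scope,
        added_value=merged_scope - (host_scope | bact_scope),
    )


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_added_value(
    host_assoc: Sequence[ScopeResult],
    free_living: Sequence[ScopeResult],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound and per-organism comparison of added values.

    For every compound appearing in at least one added value, the counts
    of organisms per group whose added value contains it are tested with
    a two-sided exact binomial on the discordant counts at p = 0.5, with
    BH correction across compounds. Also returns the per-organism
    |added value| table. Requires equal group sizes.
    """
    if len(host_assoc) != len(free_living):
        raise DesignError("compare_added_value requires equal group sizes")
    rows = []
    compounds: set[str] = set()
    for group, results in (("host", host_assoc), ("free", free_living)):
        for r in results:
            if r.added_value is None:
                raise InputError(f"ScopeResult {r.organism_ids} lacks an added value")
            compounds |= r.added_value
            rows.append(
                {
                    "organism_id": r.organism_ids[-1],
                    "lifestyle": group,
                    "n_added_value": len(r.added_value),
                }
            )
    per_organism = pd.DataFrame(rows, columns=["organism_id", "lifestyle", "n_added_value"])

    records = []
    for compound in sorted(compounds):
        n_host = sum(compound in r.added_value for r in host_assoc)
        n_free = sum(compound in r.added_value for r in free_living)
        records.append(
            {
                "compound": compound,
                "n_host": n_host,
                "n_free": n_free,
                "p_value": sign_test_p(n_host, n_host + n_free),
            }
        )
    per_compound = pd.DataFrame(
        records, columns=["compound", "n_host", "n_free", "p_value"]
    ).set_index("compound")
    if len(per_compound):
        per_compound["q_value"] = bh_adjust(per_compound["p_value"].to_numpy())
        per_compound["significant"] = per_compound["q_value"] < alpha
    else:
        per_compound["q_value"] = []
        per_compound["significant"] = []
    return per_compound, per_organism


def added_value_anova(
    counts: Sequence[float],
    class_labels: Sequence[str],
    lifestyle_labels: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (class x lifestyle) on per-organism added-value counts.

    Type-II sums of squares accommodate the unbalanced class sizes;
    Tukey HSD pairwise comparisons are reported for class. If a
    class x lifestyle cell is empty the interaction is dropped with a
    warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {
            "count": np.asarray(counts, dtype=float),
            "taxon_class": list(class_labels),
            "lifestyle": list(lifestyle_labels),
        }
    )
    if df["taxon_class"].nunique() < 2 or df["lifestyle"].nunique() < 2:
        raise DesignError("two-way ANOVA requires >= 2 levels per factor")
    cell_sizes = df.groupby(["taxon_class", "lifestyle"], observed=True).size()
    full_design = df["taxon_class"].nunique() * df["lifestyle"].nunique()
    formula = "count ~ C(taxon_class) * C(lifestyle)"
    if len(cell_sizes) < full_design:
        logger.warning("empty class x lifestyle cell(s); interaction term dropped")
        formula = "count ~ C(taxon_class) + C(lifestyle)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        # constant data yields 0/0 F statistics; report them as NaN quietly
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=2)
        tukey = pairwise_tukeyhsd(df["count"], df["taxon_class"])
    table = table.rename(
        index={
            "C(taxon_class)": "class",
            "C(lifestyle)": "lifestyle",
            "C(taxon_class):C(lifestyle)": "class:lifestyle",
            "Residual": "residual",
        }
    )
    table.index.name = "factor"
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return table, tukey_df


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_networks_tsv(path: str | Path) -> dict[str, ReactionNetwork]:
    """Read the simple network dialect (possibly several organisms per file).

    Columns: organism_id, reaction_id, substrates ("|"-separated),
    products ("|"-separated), reversible (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["organism_id", "reaction_id", "substrates", "products", "reversible"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    networks: dict[str, list[Reaction]] = defaultdict(list)
    for row in df.itertuples(index=False):
        networks[str(row.organism_id)].append(
            Reaction(
                reaction_id=str(row.reaction_id),
                substrates=frozenset(str(row.substrates).split("|")),
                products=frozenset(str(row.products).split("|")),
                reversible=str(row.reversible) in ("1", "true", "True"),
            )
        )
    return {
        org: ReactionNetwork(organism_id=org, reactions=tuple(reactions))
        for org, reactions in networks.items()
    }


def write_networks_tsv(networks: Iterable[ReactionNetwork], path: str | Path) -> None:
    rows = [
        {
            "organism_id": net.organism_id,
            "reaction_id": r.reaction_id,
            "substrates": "|".join(sorted(r.substrates)),
            "products": "|".join(sorted(r.products)),
            "reversible": int(r.reversible),
        }
        for net in networks
        for r in net.reactions
    ]
    pd.DataFrame(
        rows, columns=["organism_id", "reaction_id", "substrates", "products", "reversible"]
    ).to_csv(path, sep="\t", index=False)


def read_seeds(path: str | Path) -> SeedSet:
    """One compound id per line; blank lines and '#' comments ignored."""
    compounds = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            compounds.add(line)
    return SeedSet(compounds=frozenset(compounds))


def write_seeds(seeds: SeedSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(seeds.compounds)) + "\n")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_sbml_network(path: str | Path, organism_id: str | None = None) -> ReactionNetwork:
    """Minimal SBML reader: species references and reversibility only.

    Stoichiometric coefficients are ignored — scope expansion is
    qualitative. Works on any SBML level that uses listOfReactants /
    listOfProducts species references.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = next((el for el in root.iter() if _local(el.tag) == "model"), None)
    if model is None:
        raise FormatError(f"{path}: no <model> element")
    if organism_id is None:
        organism_id = model.get("id") or Path(path).stem
    reactions = []
    for rxn in (el for el in model.iter() if _local(el.tag) == "reaction"):
        substrates: set[str] = set()
        products: set[str] = set()
        for child in rxn:
            bucket = {"listOfReactants": substrates, "listOfProducts": products}.get(
                _local(child.tag)
            )
            if bucket is None:
                continue
            for ref in (el for el in child.iter() if _local(el.tag) == "speciesReference"):
                species = ref.get("species")
                if species:
                    bucket.add(species)
        if not substrates or not products:
            continue  # boundary/exchange pseudo-reactions
        reactions.append(
            Reaction(
                reaction_id=rxn.get("id") or f"rxn{len(reactions)}",
                substrates=frozenset(substrates),
                products=frozenset(products),
                reversible=(rxn.get("reversible", "false").lower() == "true"),
            )
        )
    return ReactionNetwork(organism_id=organism_id, reactions=tuple(reactions))
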