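"""Synthetic paired-genome datasets with known ground truth.

The generator emulates the study design end to end: genus-level pairs of
host-associated and free-living genomes spread over four bacterial
classes (genera per class 3/8/29/32, mirroring the Actinomycetia /
Alphaproteobacteria / Flavobacteriia / Gammaproteobacteria composition
of the real collection), a KO universe with class-structured background
presence probabilities plus *planted* KOs whose presence probability
differs by lifestyle, module definitions over that universe (some built
from planted KOs so module enrichment has ground truth), i.i.d.
nucleotide FASTA with a programmed GC, and host/bacterium reaction
networks with planted cross-feeding motifs whose products are
guaranteed members of the cooperation's added value.

Every generator is a pure function of (spec, seed): truth tables record
the planted effects, so recovery can be scored without re-deriving the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import GenomeMeta, ModuleDefinition
from .scope import Reaction, ReactionNetwork, SeedSet

DEFAULT_CLASS_GENERA: Mapping[str, int] = {
    "Actinomycetia": 3,
    "Alphaproteobacteria": 8,
    "Flavobacteriia": 29,
    "Gammaproteobacteria": 32,
}

# class composition of the 28+28 holobiont network collection
DEFAULT_NETWORK_CLASSES: Mapping[str, int] = {
    "Actinomycetia": 2,
    "Alphaproteobacteria": 6,
    "Flavobacteriia": 5,
    "Gammaproteobacteria": 15,
}


@dataclass(frozen=True)
class NetworkSpec:
    n_compounds: int = 60  # random-pool compounds beyond the seeds
    n_reactions: int = 40  # random background reactions per organism
    n_planted_crossfeed: int = 3  # motifs per host-associated bacterium
    n_bacteria_per_group: int = 28
    n_seeds: int = 8
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_CLASSES)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shaped defaults: 72 genus pairs, 4 classes, 5,000-KO background,
    50 planted KOs at 0.9 (host) vs 0.1 (free)."""

    n_genera: int = 72
    genomes_per_genus_per_lifestyle: int = 1
    class_genera: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_GENERA)
    )
    n_ko_background: int = 5000
    background_presence_prob: float = 0.3
    class_presence_shift: float = 0.15  # per-class jitter of background probs
    n_planted_kos: int = 50
    p_host: float = 0.9
    p_free: float = 0.1
    n_modules: int = 60
    n_planted_modules: int = 8
    steps_per_module: tuple[int, int] = (2, 6)
    alternatives_per_step: tuple[int, int] = (1, 3)
    gc_target: float = 40.0
    genome_length: int = 200_000
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.background_presence_prob, self.p_host, self.p_free):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability {p} outside [0, 1]")
        if self.n_genera < 1:
            raise InputError("at least one genus required")
        if sum(self.class_genera.values()) != self.n_genera:
            raise InputError("class_genera sizes must sum to n_genera")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    # independent named substreams so generators compose deterministically
    child = np.random.SeedSequence(spec.seed).spawn(6)
    index = {"genomes": 0, "kos": 1, "modules": 2, "fasta": 3, "networks": 4}[stream]
    return np.random.default_rng(child[index])


def background_ko_ids(spec: SyntheticSpec) -> list[str]:
    return [f"K{i:05d}" for i in range(spec.n_ko_background)]


def planted_ko_ids(spec: SyntheticSpec) -> list[str]:
    return [f"KP{i:04d}" for i in range(spec.n_planted_kos)]


def generate_paired_dataset(
    spec: SyntheticSpec,
) -> tuple[list[GenomeMeta], pd.DataFrame, pd.DataFrame]:
    """(metadata, KO matrix, KO truth table) for the paired design.

    Background KOs are present i.i.d. with a class-specific probability
    (base probability jittered per class, giving the class-level
    clustering seen in real ordinations); planted KOs are present with
    probability ``p_host`` in host-associated genomes and ``p_free`` in
    free-living ones. The truth table records each planted KO's
    probabilities and expected direction.
    """
    if spec.n_genera < 1:
        raise InputError("at least one genus required")
    rng = _rng(spec, "genomes")

    genera = [f"g{i:03d}" for i in range(spec.n_genera)]
    classes: list[str] = []
    for cls in sorted(spec.class_genera):
        classes.extend([cls] * spec.class_genera[cls])

    m = spec.genomes_per_genus_per_lifestyle
    records: list[GenomeMeta] = []
    for gi, (genus, cls) in enumerate(zip(genera, classes)):
        for k in range(m):
            pair_id = f"P{gi:03d}_{k}"
            records.append(
                GenomeMeta(
                    genome_id=f"{genus}_H{k}",
                    genus=genus,
                    taxon_class=cls,
                    lifestyle="host",
                    pair_id=pair_id,
                    source="WGS",
                )
            )
            records.append(
                GenomeMeta(
                    genome_id=f"{genus}_F{k}",
                    genus=genus,
                    taxon_class=cls,
                    lifestyle="free",
                    pair_id=pair_id,
                    source="WGS",
                )
            )

    ko_rng = _rng(spec, "kos")
    class_names = sorted(spec.class_genera)
    bg_ids = background_ko_ids(spec)
    pl_ids = planted_ko_ids(spec)
    # per-class background presence probabilities, identical across lifestyles
    class_probs = {
        cls: np.clip(
            spec.background_presence_prob
            + ko_rng.uniform(-spec.class_presence_shift, spec.class_presence_shift, len(bg_ids)),
            0.02,
            0.98,
        )
        for cls in class_names
    }
    n_genomes = len(records)
    presence = np.zeros((n_genomes, len(bg_ids) + len(pl_ids)), dtype="int8")
    for i, r in enumerate(records):
        probs = class_probs[r.taxon_class]
        presence[i, : len(bg_ids)] = ko_rng.random(len(bg_ids)) < probs
        p_planted = spec.p_host if r.lifestyle == "host" else spec.p_free
        presence[i, len(bg_ids) :] = ko_rng.random(len(pl_ids)) < p_planted

    ko = pd.DataFrame(
        presence,
        index=pd.Index([r.genome_id for r in records], name="genome_id"),
        columns=pd.Index(bg_ids + pl_ids, name="ko_id"),
    )
    if spec.p_host > spec.p_free:
        direction = "host"
    elif spec.p_host < spec.p_free:
        direction = "free"
    else:
        direction = "none"
    truth = pd.DataFrame(
        {
            "ko_id": pl_ids,
            "p_host": spec.p_host,
            "p_free": spec.p_free,
            "direction": direction,
        }
    ).set_index("ko_id")
    if direction == "none":
        truth = truth.iloc[0:0]  # a null spec plants no directional effect
    return records, ko, truth


def generate_module_definitions(
    spec: SyntheticSpec,
) -> tuple[list[ModuleDefinition], pd.DataFrame]:
    """(modules, module truth table) over the spec's KO universe.

    ``n_planted_modules`` modules draw every alternative from the planted
    KO set, so their completeness inherits the planted lifestyle effect;
    the rest draw from the background. The truth table flags the planted
    modules and their expected direction.
    """
    rng = _rng(spec, "modules")
    bg_ids = np.array(background_ko_ids(spec))
    pl_ids = np.array(planted_ko_ids(spec))
    lo_s, hi_s = spec.steps_per_module
    lo_a, hi_a = spec.alternatives_per_step
    modules: list[ModuleDefinition] = []
    rows = []
    for i in range(spec.n_modules):
        planted = i < spec.n_planted_modules and len(pl_ids) > 0
        pool = pl_ids if planted else bg_ids
        n_steps = int(rng.integers(lo_s, hi_s + 1))
        steps = []
        for _ in range(n_steps):
            n_alt = min(int(rng.integers(lo_a, hi_a + 1)), len(pool))
            steps.append(frozenset(rng.choice(pool, size=n_alt, replace=False)))
        module_id = f"M{i:04d}"
        modules.append(
            ModuleDefinition(
                module_id=module_id,
                name=("planted module" if planted else "background module"),
                steps=tuple(steps),
            )
        )
        rows.append(
            {
                "module_id": module_id,
                "planted": planted,
                "direction": (
                    "host" if planted and spec.p_host > spec.p_free
                    else "free" if planted and spec.p_host < spec.p_free
                    else "none"
                ),
            }
        )
    truth = pd.DataFrame(rows, columns=["module_id", "planted", "direction"]).set_index(
        "module_id"
    )
    return modules, truth


def generate_fasta(
    spec: SyntheticSpec,
    out_dir: str | Path,
    genome_ids: Sequence[str] | None = None,
    n_contigs: int = 4,
) -> list[Path]:
    """Write i.i.d.-nucleotide FASTA files with expected GC = gc_target."""
    if spec.genome_length <= 0:
        raise InputError("genome_length must be positive")
    rng = _rng(spec, "fasta")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genome_ids is None:
        records, _, _ = generate_paired_dataset(spec)
        genome_ids = [r.genome_id for r in records]
    g = spec.gc_target / 200.0  # per-base P(G) = P(C)
    probs = np.array([0.5 - g, g, g, 0.5 - g])  # A, C, G, T
    alphabet = np.array(list("ACGT"))
    paths = []
    for genome_id in genome_ids:
        bases = rng.choice(alphabet, size=spec.genome_length, p=probs)
        bounds = np.linspace(0, spec.genome_length, n_contigs + 1, dtype=int)
        path = out_dir / f"{genome_id}.fasta"
        with open(path, "w") as fh:
            for c in range(n_contigs):
                contig = "".join(bases[bounds[c] : bounds[c + 1]])
                if not contig:
                    continue
                fh.write(f">{genome_id}_contig{c + 1}\n")
                for start in range(0, len(contig), 80):
                    fh.write(contig[start : start + 80] + "\n")
        paths.append(path)
    return paths


@dataclass(frozen=True)
class NetworkBundle:
    host: ReactionNetwork
    bacteria: dict[str, ReactionNetwork]
    seeds: SeedSet
    organisms: pd.DataFrame  # organism_id, lifestyle, taxon_class
    truth: pd.DataFrame  # organism_id, compound (planted added-value products)


def generate_networks_with_planted_complementarity(spec: SyntheticSpec) -> NetworkBundle:
    """Host + bacterial reaction networks with guaranteed added value.

    Random background reactions are drawn over the seed + random compound
    pool only. Each host-associated bacterium additionally receives
    ``n_planted_crossfeed`` cross-feeding motifs: the host converts seeds
    into a dedicated intermediate, and the bacterium converts that
    intermediate plus a seed into a dedicated product. Because the
    intermediates and products occur nowhere else, each planted product
    is producible by the merged network only — the truth table lists
    them.
    """
    ns = spec.network
    rng = _rng(spec, "networks")
    seeds = [f"S{i:02d}" for i in range(ns.n_seeds)]
    pool = [f"C{i:03d}" for i in range(ns.n_compounds)]
    universe = seeds + pool

    def random_reactions(prefix: str, n: int) -> list[Reaction]:
        reactions = []
        for i in range(n):
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            subs = rng.choice(universe, size=n_sub, replace=False)
            prods = rng.choice(pool, size=n_prod, replace=False)
            reactions.append(
                Reaction(
                    reaction_id=f"{prefix}_r{i:03d}",
                    substrates=frozenset(map(str, subs)),
                    products=frozenset(map(str, prods)),
                    reversible=bool(rng.random() < 0.2),
                )
            )
        return reactions

    classes = []
    for cls in sorted(ns.class_sizes):
        classes.extend([cls] * ns.class_sizes[cls])
    if len(classes) != ns.n_bacteria_per_group:
        raise InputError("network class_sizes must sum to n_bacteria_per_group")

    host_reactions = random_reactions("host", ns.n_reactions)
    bacteria: dict[str, ReactionNetwork] = {}
    org_rows = []
    truth_rows = []
    for group, tag in (("host", "BH"), ("free", "BF")):
        for b in range(ns.n_bacteria_per_group):
            organism_id = f"{tag}{b:02d}"
            reactions = random_reactions(organism_id, ns.n_reactions)
            if group == "host":
                for k in range(ns.n_planted_crossfeed):
                    intermediate = f"I_{organism_id}_{k}"
                    product = f"X_{organism_id}_{k}"
                    host_reactions.append(
                        Reaction(
                            reaction_id=f"host_feed_{organism_id}_{k}",
                            substrates=frozenset({str(rng.choice(seeds))}),
                            products=frozenset({intermediate}),
                        )
                    )
                    reactions.append(
                        Reaction(
                            reaction_id=f"{organism_id}_planted_{k}",
                            substrates=frozenset({intermediate, str(rng.choice(seeds))}),
                            products=frozenset({product}),
                        )
                    )
                    truth_rows.append({"organism_id": organism_id, "compound": product})
            bacteria[organism_id] = ReactionNetwork(
                organism_id=organism_id, reactions=tuple(reactions)
            )
            org_rows.append(
                {"organism_id": organism_id, "lifestyle": group, "taxon_class": classes[b]}
            )
    host = ReactionNetwork(organism_id="host_alga", reactions=tuple(host_reactions))
    return NetworkBundle(
        host=host,
        bacteria=bacteria,
        seeds=SeedSet(compounds=frozenset(seeds)),
        organisms=pd.DataFrame(org_rows, columns=["organism_id", "lifestyle", "taxon_class"]),
        truth=pd.DataFrame(truth_rows, columns=["organism_id", "compound"]),
    )
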