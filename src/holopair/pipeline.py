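"""End-to-end orchestration: validate -> features -> modules -> OR ->
enrichment -> ordination -> scope, from a single flat JSON config.

Every stage is a pure function of (inputs, config, seed); stochastic
stages derive their seeds from the single config seed, so a rerun with
the same config reproduces byte-identical outputs. Each output table
carries a provenance header comment (package version + seed), and the
run manifest records stages, input hashes, seeds and output paths —
without timestamps, precisely so that reruns compare equal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import module_enrichment
from .errors import HolopairError, InputError
from .features import features_table
from .io import (
    filter_mag_quality,
    metadata_frame,
    read_genome_metadata,
    read_ko_table,
    read_module_definitions,
)
from .modules import completeness_matrix, filter_zero_variance
from .ordination import bray_curtis_matrix, pcoa, permanova
from .paired_or import classify_tails, median_or_over_repairings
from .scope import (
    compare_added_value,
    cooperation_scope,
    added_value_anova,
    read_networks_tsv,
    read_seeds,
)

logger = logging.getLogger(__name__)

STAGES = (
    "validate",
    "features",
    "modules",
    "paired_or",
    "enrichment",
    "ordination",
    "scope",
)


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every default equals the study's stated value."""

    metadata: str
    ko: str
    modules: str
    out_dir: str
    seed: int
    fasta_dir: str | None = None
    networks: str | None = None  # host + bacteria in one network TSV
    host_organism: str | None = None  # organism_id of the host network
    seeds_file: str | None = None
    organism_groups: str | None = None  # organism_id, lifestyle, taxon_class TSV
    presence_threshold: float = 0.75
    min_completeness: float = 50.0
    max_redundancy: float = 10.0
    lower_pct: float = 5.0
    upper_pct: float = 95.0
    n_rep: int = 100
    n_perm: int = 999
    alpha: float = 0.05

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, seed: int, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# holopair {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_sha256": {},
        "stages": [],
    }

    def record(stage: str, outputs: list[str], skipped: bool = False, note: str = "") -> None:
        manifest["stages"].append(
            {"stage": stage, "outputs": outputs, "skipped": skipped, "note": note}
        )

    for key in ("metadata", "ko", "modules", "networks", "seeds_file", "organism_groups"):
        path = getattr(config, key)
        if path:
            manifest["input_sha256"][key] = _sha256(path)

    try:
        # -- validate ------------------------------------------------------
        records = read_genome_metadata(config.metadata)
        records = filter_mag_quality(
            records, config.min_completeness, config.max_redundancy
        )
        ko = read_ko_table(config.ko, records)
        module_defs = read_module_definitions(config.modules)
        filtered_path = out_dir / "metadata_filtered.tsv"
        _write_table(metadata_frame(records), filtered_path, config.seed)
        record("validate", [filtered_path.name])

        # -- features ------------------------------------------------------
        if config.fasta_dir:
            feats = features_table(config.fasta_dir)
            feats_path = out_dir / "genome_features.tsv"
            _write_table(feats, feats_path, config.seed)
            record("features", [feats_path.name])
        else:
            record("features", [], skipped=True, note="no fasta_dir configured")

        # -- modules -------------------------------------------------------
        cm = completeness_matrix(ko, module_defs, threshold=config.presence_threshold)
        comp_path = out_dir / "module_completeness.tsv"
        _write_table(cm.df, comp_path, config.seed, index_label="genome_id")
        presence_path = out_dir / "module_presence.tsv"
        _write_table(
            cm.presence.astype(int), presence_path, config.seed, index_label="genome_id"
        )
        record("modules", [comp_path.name, presence_path.name])

        # -- paired OR -----------------------------------------------------
        or_table = median_or_over_repairings(
            ko, records, n_rep=config.n_rep, seed=config.seed
        )
        or_table = classify_tails(or_table, config.lower_pct, config.upper_pct)
        or_path = out_dir / "ko_odds_ratios.tsv"
        _write_table(or_table, or_path, config.seed, index_label="ko_id")
        record("paired_or", [or_path.name])

        # -- enrichment ----------------------------------------------------
        cm_var = filter_zero_variance(cm)
        enr = module_enrichment(cm_var, records, alpha=config.alpha)
        enr_path = out_dir / "module_enrichment.tsv"
        _write_table(enr, enr_path, config.seed, index_label="module_id")
        record("enrichment", [enr_path.name])

        # -- ordination ----------------------------------------------------
        dm = bray_curtis_matrix(cm_var)
        ord_result = pcoa(dm)
        coords_path = out_dir / "pcoa_coordinates.tsv"
        _write_table(ord_result.coordinates, coords_path, config.seed, index_label="genome_id")
        eig_path = out_dir / "pcoa_eigenvalues.tsv"
        _write_table(
            pd.DataFrame({"eigenvalue": ord_result.eigenvalues}),
            eig_path,
            config.seed,
        )
        meta_df = metadata_frame(records).set_index("genome_id").loc[list(dm.ids)]
        perm_rows = []
        for i, factor in enumerate(("lifestyle", "taxon_class")):
            res = permanova(
                dm,
                meta_df[factor].tolist(),
                n_perm=config.n_perm,
                seed=config.seed + i + 1,
            )
            perm_rows.append(
                {
                    "factor": factor,
                    "pseudo_F": res.pseudo_F,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
            )
        perm_path = out_dir / "permanova.tsv"
        _write_table(pd.DataFrame(perm_rows), perm_path, config.seed)
        record("ordination", [coords_path.name, eig_path.name, perm_path.name])

        # -- scope ---------------------------------------------------------
        if config.networks and config.seeds_file and config.organism_groups:
            networks = read_networks_tsv(config.networks)
            seeds = read_seeds(config.seeds_file)
            groups = pd.read_csv(config.organism_groups, sep="\t", comment="#")
            host_id = config.host_organism or "host_alga"
            if host_id not in networks:
                raise InputError(f"host organism {host_id!r} not found in networks")
            host_net = networks[host_id]
            results = {"host": [], "free": []}
            for row in groups.itertuples(index=False):
                res = cooperation_scope(host_net, networks[str(row.organism_id)], seeds)
                results[str(row.lifestyle)].append(res)
            per_compound, per_organism = compare_added_value(
                results["host"], results["free"], alpha=config.alpha
            )
            per_organism = per_organism.merge(
                groups[["organism_id", "taxon_class"]], on="organism_id"
            )
            anova_table, tukey = added_value_anova(
                per_organism["n_added_value"],
                per_organism["taxon_class"],
                per_organism["lifestyle"],
            )
            compound_path = out_dir / "added_value_compounds.tsv"
            _write_table(per_compound, compound_path, config.seed, index_label="compound")
            organism_path = out_dir / "added_value_counts.tsv"
            _write_table(per_organism, organism_path, config.seed)
            anova_path = out_dir / "added_value_anova.tsv"
            _write_table(anova_table, anova_path, config.seed, index_label="factor")
            tukey_path = out_dir / "added_value_tukey.tsv"
            _write_table(tukey, tukey_path, config.seed)
            record(
                "scope",
                [compound_path.name, organism_path.name, anova_path.name, tukey_path.name],
            )
        else:
            record("scope", [], skipped=True, note="no networks configured")
    except HolopairError as exc:
        stage = STAGES[len(manifest["stages"])]
        raise HolopairError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
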