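import numpy as np
import pandas as pd
import pytest

from holopair.io import GenomeMeta, ModuleDefinition


def make_metadata(n_genera: int, per_genus: int = 1, classes=None) -> list[GenomeMeta]:
    """Balanced paired metadata: per_genus host + per_genus free genomes per genus."""
    records = []
    for g in range(n_genera):
        cls = classes[g] if classes is not None else "ClassA"
        for k in range(per_genus):
            for lifestyle, tag in (("host", "H"), ("free", "F")):
                records.append(
                    GenomeMeta(
                        genome_id=f"g{g:03d}_{tag}{k}",
                        genus=f"g{g:03d}",
                        taxon_class=cls,
                        lifestyle=lifestyle,
                        pair_id=f"P{g:03d}_{k}",
                        source="WGS",
                    )
                )
    return records


def make_ko_matrix(records, ko_patterns: dict[str, dict[str, int]]) -> pd.DataFrame:
    """KO matrix from explicit {ko_id: {genome_id: 0/1}} patterns (default 0)."""
    genome_ids = [r.genome_id for r in records]
    df = pd.DataFrame(0, index=pd.Index(genome_ids, name="genome_id"),
                      columns=pd.Index(sorted(ko_patterns), name="ko_id"), dtype="int8")
    for ko_id, pattern in ko_patterns.items():
        for genome_id, value in pattern.items():
            df.loc[genome_id, ko_id] = value
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def metadata_tsv(tmp_path):
    """A minimal valid 4-genome / 2-pair metadata file."""
    path = tmp_path / "metadata.tsv"
    path.write_text(
        "genome_id\tgenus\ttaxon_class\tlifestyle\tpair_id\tsource\tcompleteness\tredundancy\thost_species\n"
        "A_h\tAlpha\tClassA\thost\tp1\tWGS\t\t\tKelp\n"
        "A_f\tAlpha\tClassA\tfree\tp1\tWGS\t\t\t\n"
        "B_h\tBeta\tClassB\thost\tp2\tMAG\t80.0\t2.0\tKelp\n"
        "B_f\tBeta\tClassB\tfree\tp2\tMAG\t65.5\t4.5\t\n"
    )
    return path


def simple_module(module_id: str, *steps) -> ModuleDefinition:
    return ModuleDefinition(
        module_id=module_id, name="", steps=tuple(frozenset(s) for s in steps)
    )
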