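import numpy as np
import pandas as pd
import pytest

from orgscreen.features import COLUMNS, LabeledTable
from orgscreen.simulate import SimulationConfig, simulate_assembly


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic assembly with evidence files on disk."""
    cfg = SimulationConfig(
        n_sequences=120,
        organellar_fraction=0.2,
        organellar_length=(12_000, 30_000),
        seed=7,
    )
    return simulate_assembly(cfg, tmp_path_factory.mktemp("bundle"))


def make_labeled_table(n_nuclear=60, n_mito=20, n_plastid=20, seed=0, separable=True) -> LabeledTable:
    """Programmatic feature table; with ``separable`` the classes occupy
    disjoint regions of feature space, otherwise all classes share one
    distribution (labels carry no signal)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    specs = [("nuclear", n_nuclear), ("mitochondrion", n_mito), ("plastid", n_plastid)]
    i = 0
    for cls, count in specs:
        for _ in range(count):
            i += 1
            sid = f"s{i:04d}"
            labels[sid] = cls
            if separable and cls != "nuclear":
                gc = rng.normal(0.21, 0.01)
                z = rng.normal(-10, 0.5)
                length = int(rng.integers(12_000, 40_000))
                mito_hits = int(rng.poisson(5)) + 1 if cls == "mitochondrion" else 0
                plastid_hits = int(rng.poisson(5)) + 1 if cls == "plastid" else 0
            else:
                gc = rng.normal(0.41, 0.01)
                z = rng.normal(0, 1)
                length = int(rng.integers(2_000, 200_000))
                mito_hits = plastid_hits = 0
            rows.append(
                {
                    "seq_id": sid,
                    "length_bp": length,
                    "gc": gc,
                    "gc_delta": gc - 0.41,
                    "gc_zscore": z,
                    "gc_outlier_flag": int(abs(z) > 2),
                    "repeat_density": float(rng.uniform(0, 2000)),
                    "repeat_frac": float(rng.uniform(0, 0.5)),
                    "rrna_density": float(rng.uniform(0, 5)),
                    "trna_density": float(rng.uniform(0, 50)),
                    "cpg_density": float(rng.uniform(0, 20)),
                    "mito_hit_density": mito_hits * 1e6 / length,
                    "plastid_hit_density": plastid_hits * 1e6 / length,
                    "mito_hit_count": mito_hits,
                    "plastid_hit_count": plastid_hits,
                    "best_mito_bitscore": 300.0 if mito_hits else 0.0,
                    "best_plastid_bitscore": 300.0 if plastid_hits else 0.0,
                }
            )
    return LabeledTable(frame=pd.DataFrame(rows, columns=COLUMNS), labels=labels)


@pytest.fixture(scope="session")
def separable_table() -> LabeledTable:
    return make_labeled_table(seed=1, separable=True)
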