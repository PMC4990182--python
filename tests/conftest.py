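import numpy as np
import pandas as pd
import pytest

from polyadapt.io_formats import GenotypePanel


def make_panel(dosage_columns: dict[str, list[int]],
               chroms: dict[str, str] | None = None,
               positions: dict[str, int] | None = None) -> GenotypePanel:
    """Build a small panel from named dosage columns (test helper)."""
    ids = list(dosage_columns)
    n = len(next(iter(dosage_columns.values())))
    variants = pd.DataFrame({
        "variant_id": ids,
        "chrom": [(chroms or {}).get(v, "1") for v in ids],
        "pos": [(positions or {}).get(v, 1000 * (i + 1))
                for i, v in enumerate(ids)],
    })
    dosages = np.column_stack([np.asarray(dosage_columns[v], dtype=np.int8)
                               for v in ids])
    return GenotypePanel(sample_ids=[f"S{i}" for i in range(n)],
                         variants=variants, dosages=dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
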