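import numpy as np
import pandas as pd
import pytest

from mrscreen.data import COLUMNS, SummaryStatSet
from mrscreen.harmonize import from_arrays


def make_stats(rows, name="trait", trait_type="quantitative"):
    """SummaryStatSet from a list of per-SNP dicts with defaults filled in."""
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.02, pvalue=1e-9, n=10_000)
    full = []
    for i, row in enumerate(rows):
        rec = {**defaults, "snp_id": f"rs{i + 1}", "pos": 1000 + i * 50_000_000, **row}
        full.append(rec)
    return SummaryStatSet(name, trait_type, pd.DataFrame(full, columns=COLUMNS))


def make_harmonized(bx, by, sx=None, sy=None, **kw):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full_like(bx, 0.05) if sy is None else np.asarray(sy, float)
    return from_arrays(bx, sx, by, sy, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
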