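import numpy as np
import pandas as pd
import pytest

from deeptag.containers import CountMatrix


@pytest.fixture()
def sample_sheet() -> pd.DataFrame:
    rows = []
    for g in ("WT", "MUT"):
        for t in ("SHAM", "CSD"):
            for r in (1, 2, 3):
                rows.append((f"{g}.{t}.{r}", g, t))
    return pd.DataFrame(
        [(g, t) for _, g, t in rows],
        index=pd.Index([s for s, _, _ in rows], name="sample"),
        columns=["genotype", "treatment"],
    )


@pytest.fixture()
def small_counts(sample_sheet) -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, len(sample_sheet))),
        index=pd.Index([f"g{i}" for i in range(30)], name="gene"),
        columns=sample_sheet.index,
    )
    chroms = pd.Series(["8" if i % 10 == 0 else str(i % 5 + 1) for i in range(30)],
                       index=counts.index)
    return CountMatrix(counts, sample_sheet, chroms)
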