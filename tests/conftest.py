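import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gerosig import ContextKey, DEGThresholds, SignatureTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(genes, log2fc, pvalue=None, fdr=None, **ctx_kwargs):
    """Build a small SignatureTable; missing stats default to significant."""
    n = len(genes)
    ctx_defaults = dict(study_id="s", group="g", unit="liver",
                        modality="bulk", role="OTHER", intervention="")
    ctx_defaults.update(ctx_kwargs)
    df = pd.DataFrame({
        "gene": list(genes),
        "log2fc": np.asarray(log2fc, dtype=float),
        "pvalue": np.full(n, 1e-6) if pvalue is None else np.asarray(pvalue),
        "fdr": np.full(n, 1e-6) if fdr is None else np.asarray(fdr),
    })
    return SignatureTable(ContextKey(**ctx_defaults), df)


@pytest.fixture
def thresholds():
    return DEGThresholds()
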