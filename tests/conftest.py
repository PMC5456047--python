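import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dyadsync.predict import FEATURE_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_feature_table(n_dyads=40, dprime=2.0, seed=0,
                       informative="head_bin_-2", permute_label=None):
    """Synthetic 20-feature table: standard-normal noise plus an optional
    class separation of ``dprime`` on one feature (veracity label)."""
    r = np.random.default_rng(seed)
    rows = []
    for d in range(n_dyads):
        for order, ver in enumerate(("deception", "truth"), start=1):
            feats = {f: r.normal() for f in FEATURE_COLUMNS}
            if dprime:
                feats[informative] += dprime / 2 if ver == "deception" else -dprime / 2
            rows.append(dict(dyad_id=f"d{d:03d}",
                             conversation_id=f"d{d:03d}_c{order}",
                             veracity=ver,
                             conflict="disagree" if d % 2 == 0 else "agree",
                             **feats))
    df = pd.DataFrame(rows)
    if permute_label:
        df[permute_label] = r.permutation(df[permute_label].to_numpy())
    return df
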