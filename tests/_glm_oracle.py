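"""Independent general-linear-model oracle for split-plot ANOVA.

Computes effect sums of squares on a balanced design by orthogonal
projection onto sum-coded contrast subspaces of the subject-level data
vector — a route entirely separate from the cell-means algorithm under
test.
"""

import numpy as np
import pandas as pd


def _sum_code(levels: pd.Series) -> np.ndarray:
    """(n, k-1) sum-coded contrast columns for a factor."""
    cats = sorted(levels.unique())
    k = len(cats)
    out = np.zeros((len(levels), k - 1))
    for j, c in enumerate(cats[:-1]):
        out[:, j] = (levels == c).astype(float)
    out[(levels == cats[-1]).to_numpy(), :] = -1.0
    return out


def _interaction(*mats: np.ndarray) -> np.ndarray:
    acc = mats[0]
    for m in mats[1:]:
        acc = np.einsum("ni,nj->nij", acc, m).reshape(len(acc), -1)
    return acc


def glm_projection_ss(data: pd.DataFrame, dv="value", subject="subject_id",
                      within="time_bin", between=()) -> dict[str, float]:
    """SS per effect via projection; valid for balanced designs only."""
    df = data.sort_values([subject, within]).reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)
    y = y - y.mean()
    coded = {f: _sum_code(df[f]) for f in (*between, within)}

    ss = {}
    factors = list(between) + [within]
    from itertools import combinations

    for r in range(1, len(factors) + 1):
        for combo in combinations(factors, r):
            X = _interaction(*[coded[f] for f in combo])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            ss[" * ".join(combo)] = float(np.sum((X @ beta) ** 2))
    return ss
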