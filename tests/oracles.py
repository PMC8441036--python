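"""Independent reference implementations used to cross-check the package.

These are deliberately naive — plain loops, explicit formulas, their own
table parsing — and share no code path with the implementations they
verify.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np
from scipy import stats as sps


def load_feature_dicts():
    """Parse the packaged feature table with the csv module (not the package)."""
    path = resources.files("cvcscore").joinpath("data", "feature_table.tsv")
    features = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["class"] == "consonant":
                features[row["symbol"]] = {
                    "class": "consonant",
                    "voicing": row["voicing"],
                    "place": row["place"],
                    "manner": row["manner"],
                }
            else:
                features[row["symbol"]] = {
                    "class": "vowel",
                    "height": row["height"],
                    "advancement": row["advancement"],
                    "rounding": row["rounding"],
                    "tenseness": row["tenseness"],
                }
    return features


def brute_force_score(target, production, features):
    """Feature-by-feature raw total for a CVC target, by direct comparison.

    Re-implements slot alignment with explicit loops over the production.
    """
    c1 = v = c2 = None
    for sym in production:
        if features[sym]["class"] == "vowel":
            if v is None:
                v = sym
        else:
            if v is None and c1 is None:
                c1 = sym
            elif v is not None and c2 is None:
                c2 = sym
    total = 0
    for t_sym, p_sym in zip(target, (c1, v, c2)):
        t = features[t_sym]
        if p_sym is None or features[p_sym]["class"] != t["class"]:
            continue
        p = features[p_sym]
        for key in t:
            if key != "class" and t[key] == p[key]:
                total += 1
    return total


def icc_mean_squares(matrix):
    """ICC(A,1) / ICC(A,k) from explicitly accumulated ANOVA sums of squares."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return single, average


def regression_blocks(data, outcome, blocks):
    """Blockwise OLS by explicit normal equations on z-scored variables.

    Returns a list of dicts per block with r2, delta_r2, delta_f, df, and
    per-predictor beta, se, p, part.
    """

    def zscore(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    z = {c: zscore(data[c]) for c in data.columns}
    y = z[outcome]
    n = len(y)

    def fit(names):
        if not names:
            return 0.0, None, None
        X = np.column_stack([np.ones(n)] + [z[p] for p in names])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst
        se = np.sqrt(np.diag(xtx_inv) * sse / (n - len(names) - 1))
        return r2, beta, se

    out = []
    cumulative = []
    prev_r2 = 0.0
    for block in blocks:
        cumulative = cumulative + list(block)
        r2, beta, se = fit(cumulative)
        k_full = len(cumulative)
        df_den = n - k_full - 1
        delta_r2 = r2 - prev_r2
        delta_f = (delta_r2 / len(block)) / ((1.0 - r2) / df_den)
        preds = []
        for i, name in enumerate(cumulative, start=1):
            r2_without, _, _ = fit([p for p in cumulative if p != name])
            part = np.sign(beta[i]) * np.sqrt(max(r2 - r2_without, 0.0))
            t = beta[i] / se[i]
            preds.append({
                "name": name,
                "beta": float(beta[i]),
                "se": float(se[i]),
                "p": float(2 * sps.t.sf(abs(t), df_den)),
                "part": float(part),
            })
        out.append({
            "r2": r2, "delta_r2": delta_r2, "delta_f": float(delta_f),
            "df": (len(block), df_den), "predictors": preds,
        })
        prev_r2 = r2
    return out
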