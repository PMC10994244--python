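"""CDK4 phosphorylation profile classification from 2D-gel spot ratios.

On 2D gels, spot 3 is the activating T172-phosphorylated CDK4 form and
spot 2 a modified but unphosphorylated form; the background-subtracted
volume ratio spot3/spot2 stratifies tumours into three profiles:

    A (Absent):  r < 0.025
    L (Low):     0.025 <= r <= 0.5
    H (High):    r > 0.5

Profile H/L tumours carry active CDK4 and are predicted sensitive to
CDK4/6 inhibitors.  The ratio correlates with a transcriptomic
proliferation score — the median library-normalized expression of a
cell-cycle-progression (CCP) gene signature — which this module also
computes and correlates (Spearman) with the spot ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PROFILE_ABSENT_BELOW = 0.025
PROFILE_HIGH_ABOVE = 0.5


@dataclass
class SpotQuantRecord:
    sample_id: str
    spot2_volume: float
    spot3_volume: float
    ratio: float | None  # None when spot2 volume is 0 (undefined)
    profile: str | None  # 'A' | 'L' | 'H' | None when ratio undefined


def classify_profile(ratio: float) -> str:
    """Map a spot3/spot2 ratio to profile A, L or H.

    The boundary convention keeps L closed on both ends: exactly 0.025
    and exactly 0.5 are both L.  The three intervals partition [0, inf).
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError(f"ratio must be finite and >= 0, got {ratio!r}")
    if ratio < PROFILE_ABSENT_BELOW:
        return "A"
    if ratio <= PROFILE_HIGH_ABOVE:
        return "L"
    return "H"


def classify_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Classify every sample of a spot-quantification table.

    Expects columns ``sample_id``, ``spot2_volume``, ``spot3_volume``
    (background-subtracted).  Samples with spot2 volume 0 get an
    undefined ratio and no profile, flagged in ``ratio_defined``.
    """
    out = spots.copy()
    if (out["spot2_volume"] < 0).any() or (out["spot3_volume"] < 0).any():
        raise ValueError("spot volumes must be background-subtracted and >= 0")
    defined = out["spot2_volume"] > 0
    out["ratio"] = np.where(
        defined, out["spot3_volume"] / out["spot2_volume"].replace(0, np.nan), np.nan
    )
    out["ratio_defined"] = defined
    out["profile"] = [
        classify_profile(r) if d else None
        for r, d in zip(out["ratio"], defined)
    ]
    return out


def ccp_score(
    expression: pd.DataFrame,
    signature: list[str],
    log2: bool = False,
) -> pd.DataFrame:
    """Proliferation score: per-sample median expression of a CCP signature.

    ``expression`` is a genes x samples matrix on the CP20M scale.
    Signature genes absent from the matrix are reported, not imputed;
    with zero genes found the score is undefined and an error is raised.
    The median is taken on the linear CP20M scale by default (``log2``
    switches to log2(x + 1) first).
    """
    found = [g for g in signature if g in expression.index]
    if not found:
        raise ValueError("no signature gene found in the expression matrix")
    sub = expression.loc[found]
    if log2:
        sub = np.log2(sub + 1.0)
    scores = sub.median(axis=0)
    return pd.DataFrame(
        {
            "sample_id": scores.index,
            "score": scores.to_numpy(),
            "n_genes_found": len(found),
        }
    ).reset_index(drop=True)


def correlate_ratio_score(
    classified: pd.DataFrame,
    scores: pd.DataFrame,
    classes: tuple[str, ...] = ("H", "L"),
) -> tuple[float, float, int]:
    """Spearman rank correlation between spot ratio and CCP score.

    Restricted by default to the H and L profiles (samples with
    detectable CDK4 phosphorylation).  Returns (rho, two-sided p, n).
    Mid-ranks handle ties; a constant vector leaves rho undefined.
    """
    merged = classified.merge(scores, on="sample_id", how="inner")
    merged = merged[merged["profile"].isin(classes)]
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 paired samples in classes {classes}, got {len(merged)}"
        )
    x = merged["ratio"].to_numpy(dtype=float)
    y = merged["score"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), len(merged)


def read_signature(path) -> list[str]:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes
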