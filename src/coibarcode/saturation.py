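"""Entropy-based index of substitution saturation and its significance test.

The index compares the mean per-site Shannon entropy of the alignment with
the entropy the alignment would show at full saturation, when every site
has been randomized to the overall base composition:

    ISS = mean_l H_l / H_FSS,    H_FSS = -sum_b f_b ln f_b

ISS near 0 means sites are still mostly invariant (strong phylogenetic
signal); ISS approaching 1 means site patterns are indistinguishable from
random draws (signal lost). The statistic is compared with a critical value
ISSc supplied by the user — ISSc depends on taxon number and topology and
comes from published simulation tables, not from this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import Alignment

logger = logging.getLogger(__name__)


@dataclass
class SaturationResult:
    iss: float
    iss_c: float
    t_stat: float
    df: int
    p_value: float
    per_site_entropy: np.ndarray

    @property
    def saturated(self) -> bool:
        """True when ISS is not significantly below the critical value."""
        return not (self.iss < self.iss_c and self.p_value < 0.05)

    def report(self) -> str:
        verdict = (
            "significant saturation cannot be ruled out"
            if self.saturated
            else "no significant substitution saturation (usable signal)"
        )
        return (
            f"ISS = {self.iss:.3f}  ISSc = {self.iss_c:.3f}  "
            f"T = {self.t_stat:.1f}  d.f. = {self.df}  P = {self.p_value:.2g}\n"
            f"verdict: {verdict}"
        )


def site_entropy(alignment: Alignment) -> np.ndarray:
    """Shannon entropy (natural log) per site over unambiguous base frequencies.

    Gaps and ambiguity codes are excluded per site; a site with no
    countable base gets entropy 0 (logged).
    """
    enc = alignment.encoded()
    L = alignment.length
    out = np.zeros(L)
    for site in range(L):
        col = enc[:, site]
        counts = np.bincount(col[col < 4], minlength=4).astype(float)
        total = counts.sum()
        if total == 0:
            logger.warning("site %d has no countable bases; entropy set to 0", site + 1)
            continue
        p = counts[counts > 0] / total
        out[site] = float(-(p * np.log(p)).sum())
    return out


def full_saturation_entropy(alignment: Alignment) -> float:
    """Entropy of the alignment's overall base composition (-sum f ln f)."""
    enc = alignment.encoded()
    counts = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
    f = counts[counts > 0] / counts.sum()
    return float(-(f * np.log(f)).sum())


def iss_test(alignment: Alignment, iss_c: float) -> SaturationResult:
    """Test the saturation index against a supplied critical value.

    t = (ISSc - ISS) / SE(ISS) with SE from the per-site entropy sample
    variance scaled by 1/H_FSS, on df = L (alignment length); two-sided p
    from Student's t. A large positive t with small p means the alignment
    is significantly less saturated than the critical level.
    """
    if not (0.0 < iss_c <= 1.0):
        raise ValueError(f"iss_c must lie in (0, 1], got {iss_c}")
    h = site_entropy(alignment)
    h_fss = full_saturation_entropy(alignment)
    L = alignment.length
    iss = float(h.mean() / h_fss)
    se = float(h.std(ddof=1) / h_fss / math.sqrt(L)) if L > 1 else 0.0
    if se == 0.0:
        t_stat = math.inf if iss_c != iss else 0.0
        p = 0.0 if t_stat else 1.0
    else:
        t_stat = (iss_c - iss) / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df=L))
    return SaturationResult(
        iss=iss, iss_c=iss_c, t_stat=t_stat, df=L, p_value=p, per_site_entropy=h
    )
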