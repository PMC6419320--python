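"""Per-SOC Fisher's exact test for Boxed-Warning term enrichment.

For each disorder System Organ Class the 2x2 table partitions the PT
universe U (by default, the PTs observed anywhere in the corpus) by SOC
membership and by presence in any Boxed Warning section:

===============  ============  ================
                 in BW          not in BW
===============  ============  ================
PT in SOC        a              b
PT not in SOC    c              d
===============  ============  ================

The two-sided p-value sums hypergeometric point probabilities of all
tables with the observed margins whose point probability does not exceed
that of the observed table; the sum is accumulated in log-space.  Multiple
testing across SOCs is handled by Bonferroni correction (threshold =
alpha / number of SOCs tested; 0.05 / 22 rounds to the conventional 0.002).
"""

from __future__ import annotations

import logging
import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .meddra import Dictionary
from .occurrence import DrugPTMatrix, WHOLE

logger = logging.getLogger(__name__)

#: Relative tolerance on the "point probability <= observed" comparison.
_POINT_PROB_RTOL = 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value of one 2x2 contingency table.

    Computed by summing, in log-space, hypergeometric point probabilities
    over the attainable tables with the observed margins whose probability
    is no greater than the observed table's (within relative tolerance
    1e-7).  Degenerate margins (an empty row or column) give p = 1.
    """
    cells = (a, b, c, d)
    if any(not float(x).is_integer() or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("at least one cell must be positive")
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (n_total - row1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    logp = hypergeom.logpmf(ks, n_total, row1, col1)
    cutoff = logp[a - kmin] + math.log1p(_POINT_PROB_RTOL)
    p = float(np.exp(logsumexp(logp[logp <= cutoff])))
    return min(p, 1.0)


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p-value: P(A >= a) given the margins."""
    n_total = a + b + c + d
    return float(hypergeom.sf(a - 1, n_total, a + b, a + c))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def round_one_sig_digit(x: float) -> float:
    """Round to one significant digit (0.05/22 -> 0.002)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def enrich_socs(
    m: DrugPTMatrix,
    d: Dictionary,
    alpha: float = 0.05,
    universe: Literal["observed", "dictionary"] = "observed",
    alternative: Literal["two-sided", "greater"] = "two-sided",
) -> pd.DataFrame:
    """Per-disorder-SOC enrichment table for Boxed Warning PT membership.

    ``universe='observed'`` takes U as the PTs observed anywhere in the
    corpus (whole-document slice); ``'dictionary'`` uses every disorder PT
    in the terminology.  Returns one row per disorder SOC with the 2x2
    cells, p-value, and significance verdicts at ``alpha`` (unadjusted) and
    at the Bonferroni-corrected threshold; the corrected threshold, its
    one-significant-digit form and the number of tests are stored in
    ``DataFrame.attrs``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if universe == "observed":
        u_pts = {p for p in m.section_pt_set(WHOLE) if d.is_disorder_pt(p)}
    elif universe == "dictionary":
        u_pts = {p for p in d.pts if d.is_disorder_pt(p)}
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if not u_pts:
        raise ValueError("empty PT universe; nothing to test")

    bw_pts = m.section_pt_set("BW") & u_pts
    bw_slice = m.section_slice("BW")
    test = fisher_exact_2x2 if alternative == "two-sided" else fisher_exact_greater

    soc_codes = sorted(d.disorder_soc_codes)
    n_tests = len(soc_codes)
    threshold = bonferroni_threshold(alpha, n_tests)

    rows = []
    for soc in soc_codes:
        soc_pts = {p for p in u_pts if d.pt_primary_soc(p) == soc}
        a = len(soc_pts & bw_pts)
        b = len(soc_pts - bw_pts)
        c = len(bw_pts - soc_pts)
        dd = len(u_pts) - a - b - c
        if not soc_pts:
            logger.warning(
                "SOC %d (%s) has no PTs in the universe; p set to 1.0",
                soc, d.soc_name(soc),
            )
            p = 1.0
        else:
            p = test(a, b, c, dd)
        soc_drug_mask = np.zeros(len(m.set_ids), dtype=bool)
        if soc_pts:
            cols = [m._pt_ix[p_] for p_ in soc_pts if p_ in m._pt_ix]
            if cols:
                soc_drug_mask = bw_slice[:, cols].any(axis=1)
        rows.append({
            "soc_code": soc,
            "soc_name": d.soc_name(soc),
            "soc_abbrev": d.socs[soc].soc_abbrev,
            "a": a, "b": b, "c": c, "d": dd,
            "p_value": p,
            "significant_unadj": p < alpha,
            "significant_bonf": p < threshold,
            "n_pts_in_soc": a + b,
            "n_drugs_in_soc": int(soc_drug_mask.sum()),
        })
    table = pd.DataFrame(rows)
    table.attrs.update({
        "alpha": alpha,
        "n_tests": n_tests,
        "bonferroni_threshold": threshold,
        "bonferroni_threshold_1sig": round_one_sig_digit(threshold),
        "universe": universe,
        "alternative": alternative,
        "universe_size": len(u_pts),
        "n_bw_pts": len(bw_pts),
    })
    return table
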