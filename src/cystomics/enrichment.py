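"""Term overrepresentation testing by the binomial test with Bonferroni
correction, generic over any user-supplied feature -> term annotation table
(e.g. a GO-Slim molecular-function export).

Per term with background frequency p0, the over-direction p-value is
P(X >= k) and the under-direction p-value is P(X <= k) for X ~
Binomial(|query|, p0); the smaller tail is reported with its direction, and
Bonferroni multiplies by the number of terms actually tested.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binom


def binomial_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of annotation terms in ``query`` against
    ``background``.

    Terms with zero background count are skipped (their expected frequency
    is undefined). Returns a frame sorted by Bonferroni-adjusted p with
    columns term, k, n, expected, direction, p, p_bonf, significant.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(f"query features absent from background: {sorted(stray)[:10]}")
    if not background:
        raise ValueError("empty background")
    n = len(query)

    term_bg: dict[str, int] = {}
    term_q: dict[str, int] = {}
    for feat in background:
        for term in annotations.get(feat, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if feat in query:
                term_q[term] = term_q.get(term, 0) + 1

    rows = []
    for term, bg_count in sorted(term_bg.items()):
        if bg_count == 0:
            continue
        p0 = bg_count / len(background)
        k = term_q.get(term, 0)
        p_over = float(binom.sf(k - 1, n, p0))   # P(X >= k)
        p_under = float(binom.cdf(k, n, p0))     # P(X <= k)
        if p_over <= p_under:
            direction, p = "over", p_over
        else:
            direction, p = "under", p_under
        p = min(p, 1.0)
        rows.append((term, k, n, n * p0, direction, p))

    out = pd.DataFrame(rows, columns=["term", "k", "n", "expected", "direction", "p"])
    m = len(out)
    out["p_bonf"] = (out["p"] * m).clip(upper=1.0)
    out["significant"] = out["p_bonf"] <= alpha
    return out.sort_values(["p_bonf", "term"], kind="stable").reset_index(drop=True)
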