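"""Two-tailed Fisher-exact term enrichment with Benjamini-Hochberg FDR control.

The exact test is computed in integer arithmetic: with fixed margins every
attainable 2x2 table has hypergeometric mass C(r1, a) * C(r2, c) / C(N, n1),
so comparing masses reduces to comparing integer numerators, and the
two-tailed p (probability-mass method) is an exact integer sum divided by
the common denominator.  This avoids the floating-point tie ambiguities of
pmf-based implementations while agreeing with them everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.multitest import multipletests

from .formats_io import GOAnnotationRecord, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact_two_tailed",
    "bh_fdr",
    "go_enrichment",
    "term_word_frequencies",
    "STOP_WORDS",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for one term: test with/without term, reference-rest with/without."""

    a: int  # test features carrying the term
    b: int  # test features without it
    c: int  # non-test reference features carrying the term
    d: int  # non-test reference features without it

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    table: ContingencyTable2x2
    p_two_tailed: float
    q_value: float
    direction: str  # "over" | "under"


def fisher_exact_two_tailed(t: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p by the probability-mass method.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table.  Computed
    exactly (integer numerator comparison), then clipped to 1.  Degenerate
    margins (an empty row or column) give p = 1.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    n1 = t.a + t.c
    n = t.n
    if r1 == 0 or r2 == 0 or n1 == 0 or n1 == n:
        return 1.0
    lo = max(0, n1 - r2)
    hi = min(r1, n1)
    observed = math.comb(r1, t.a) * math.comb(r2, t.c)
    total = 0
    for a in range(lo, hi + 1):
        num = math.comb(r1, a) * math.comb(r2, n1 - a)
        if num <= observed:
            total += num
    p = total / math.comb(n, n1)
    return min(p, 1.0)


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value outside [0, 1]: {p}")
    if not pvalues:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(x) for x in q]


def go_enrichment(
    test_ids: set[str],
    reference_ids: set[str],
    annotations: list[GOAnnotationRecord],
    fdr_threshold: float = 0.05,
    exclusive_reference: bool = True,
) -> list[EnrichmentResult]:
    """Fisher/BH enrichment of every term seen in the test set.

    The contingency reference side is ``reference_ids \\ test_ids`` by
    default, keeping the four cells disjoint; ``exclusive_reference=False``
    counts the whole reference set instead.  Terms with q strictly below
    ``fdr_threshold`` are returned sorted by q then term, with direction
    "over" iff the term's rate in the test set exceeds its rate in the
    comparison set.
    """
    if not test_ids <= reference_ids:
        raise ValidationError("test set must be a subset of the reference set")
    terms_by_feature = {r.feature_id: r.terms for r in annotations}
    rest = reference_ids - test_ids if exclusive_reference else reference_ids

    term_test: dict[str, int] = {}
    for fid in test_ids:
        for term in terms_by_feature.get(fid, ()):
            term_test[term] = term_test.get(term, 0) + 1
    if not term_test:
        return []
    term_rest: dict[str, int] = {t: 0 for t in term_test}
    for fid in rest:
        for term in terms_by_feature.get(fid, ()):
            if term in term_rest:
                term_rest[term] += 1

    terms = sorted(term_test)
    n_test, n_rest = len(test_ids), len(rest)
    tables = [
        ContingencyTable2x2(
            a=term_test[t],
            b=n_test - term_test[t],
            c=term_rest[t],
            d=n_rest - term_rest[t],
        )
        for t in terms
    ]
    pvals = [fisher_exact_two_tailed(tb) for tb in tables]
    qvals = bh_fdr(pvals)

    results = []
    for term, tb, p, q in zip(terms, tables, pvals, qvals):
        if q < fdr_threshold:
            test_rate = tb.a / (tb.a + tb.b) if tb.a + tb.b else 0.0
            rest_rate = tb.c / (tb.c + tb.d) if tb.c + tb.d else 0.0
            results.append(
                EnrichmentResult(
                    term=term,
                    table=tb,
                    p_two_tailed=p,
                    q_value=q,
                    direction="over" if test_rate > rest_rate else "under",
                )
            )
    results.sort(key=lambda r: (r.q_value, r.term))
    return results


#: Minimal English stop-word list for GO-term word summaries.
STOP_WORDS = frozenset(
    "a an and by for in of on or the to via with within".split()
)


def term_word_frequencies(
    results: list[EnrichmentResult], term_names: dict[str, str]
) -> list[tuple[str, int]]:
    """Word counts over enriched-term names (the word-cloud summary input).

    Names are lowercased and whitespace-tokenized; stop words are removed.
    Returned descending by count, ties alphabetical.
    """
    counts: dict[str, int] = {}
    for r in results:
        name = term_names.get(r.term, "")
        for word in name.lower().split():
            if word and word not in STOP_WORDS:
                counts[word] = counts.get(word, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
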