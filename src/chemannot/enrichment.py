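"""Annotation-term enrichment of a chemical set against a background.

For each annotation term the 2x2 contingency counts are

    k  input chemicals carrying the term        n  input set size
    K  background chemicals carrying the term   N  background size

and significance of over-representation is the one-sided Fisher's exact
test, i.e. the upper tail P(X >= k) of the hypergeometric distribution with
parameters (N, K, n).  Multiple testing across *all* terms of *all*
databases is controlled jointly by the Benjamini-Hochberg step-up FDR
procedure.  The typical background is the full library screened in an
experiment; by default ("auto") it is the union of all annotated chemicals
in the bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, lgamma, log

import numpy as np
import pandas as pd

from .annotation_store import AnnotationBundle, AnnotationTerm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (k, n, K, N) for one term's enrichment test."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        for name in ("k", "n", "K", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValueError(f"count {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"count {name} must be non-negative, got {v}")
        if self.n > self.N:
            raise ValueError(f"n={self.n} exceeds N={self.N}")
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds N={self.N}")
        if self.k > min(self.n, self.K):
            raise ValueError(f"k={self.k} exceeds min(n={self.n}, K={self.K})")


def _log_binom(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def fisher_enrichment_p(table: ContingencyTable) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= k).

    Summed over the exact support via log-gamma binomial coefficients, which
    is numerically stable far into the tail (relative error ~1e-13 even for
    probabilities near 1e-30).  k = 0 returns exactly 1.
    """
    k, n, K, N = table.k, table.n, table.K, table.N
    if k <= max(0, n + K - N):
        return 1.0  # k at or below the support minimum: the whole tail
    log_denominator = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denominator
        for i in range(k, min(n, K) + 1)
    ]
    top = max(log_terms)
    p = exp(top) * sum(exp(t - top) for t in log_terms)
    return min(p, 1.0)


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment.

    adj_(i) = min_{j >= i} m * p_(j) / j over the ascending order, capped at
    1, returned in the original input order.  Permutation-equivariant: ties
    receive identical adjusted values regardless of input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return []
    if np.any((p <= 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        bad = p[(p <= 0.0) | (p > 1.0) | np.isnan(p)][0]
        raise ValueError(f"p-values must lie in (0, 1], got {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adj_sorted
    return adjusted.tolist()


@dataclass
class EnrichmentResult:
    """One term's enrichment outcome."""

    term: AnnotationTerm
    table: ContingencyTable
    p_value: float
    adjusted_p: float
    fold_enrichment: float
    members: list[str]
    enriched: bool = False


def run_enrichment(
    input_ids: set[str],
    background_ids: set[str] | str,
    bundle: AnnotationBundle,
    alpha: float = 0.05,
    min_term_size: int = 2,
    strict_background: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in the input set.

    ``background_ids`` may be the literal string ``"auto"``, meaning the
    union of annotated chemicals across the bundle.  Input chemicals absent
    from the background are added to it with a warning (or rejected in
    strict mode).  One test is run per (database, term) with at least
    ``min_term_size`` background carriers; BH adjustment is applied jointly
    across all databases.  Results are sorted by adjusted p (ties by
    database then term id); terms at adjusted_p <= alpha are flagged
    enriched, but the full table is returned.
    """
    input_ids = set(input_ids)
    if not input_ids:
        raise ValueError("input set is empty")
    if isinstance(background_ids, str):
        if background_ids != "auto":
            raise ValueError(f"background_ids must be a set or 'auto'")
        background = bundle.annotated_chemicals()
    else:
        background = set(background_ids)
    missing = sorted(input_ids - background)
    if missing:
        if strict_background:
            raise ValueError(
                "input chemicals absent from background: " + ", ".join(missing)
            )
        logger.warning(
            "%d input chemicals absent from background were added: %s",
            len(missing),
            ", ".join(missing),
        )
        background |= set(missing)
    n, N = len(input_ids), len(background)

    results: list[EnrichmentResult] = []
    for db in bundle:
        for term_id, carriers in sorted(db.term_to_chems().items()):
            bg_carriers = carriers & background
            K = len(bg_carriers)
            if K < min_term_size:
                continue
            members = sorted(bg_carriers & input_ids)
            table = ContingencyTable(k=len(members), n=n, K=K, N=N)
            fold = (table.k / n) / (K / N)
            results.append(
                EnrichmentResult(
                    term=db.terms[term_id],
                    table=table,
                    p_value=fisher_enrichment_p(table),
                    adjusted_p=float("nan"),
                    fold_enrichment=fold,
                    members=members,
                )
            )
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, adj in zip(results, adjusted):
            r.adjusted_p = adj
            r.enriched = adj <= alpha
    results.sort(key=lambda r: (r.adjusted_p, r.term.database, r.term.term_id))
    logger.info(
        "enrichment: %d tests (n=%d, N=%d), %d terms at adjusted_p <= %g",
        len(results),
        n,
        N,
        sum(r.enriched for r in results),
        alpha,
    )
    return results


ENRICHMENT_COLUMNS = (
    "database",
    "category",
    "term_id",
    "term_label",
    "k",
    "n",
    "K",
    "N",
    "fold_enrichment",
    "p_value",
    "adjusted_p",
    "enriched",
    "members",
)


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (
            r.term.database,
            r.term.category,
            r.term.term_id,
            r.term.label,
            r.table.k,
            r.table.n,
            r.table.K,
            r.table.N,
            r.fold_enrichment,
            r.p_value,
            r.adjusted_p,
            r.enriched,
            ";".join(r.members),
        )
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS))


def write_enrichment_table(results: list[EnrichmentResult], path: str) -> None:
    """Deterministic TSV export of an enrichment result list."""
    df = enrichment_table(results)
    for col in ("fold_enrichment", "p_value", "adjusted_p"):
        df[col] = df[col].map(lambda x: f"{x:.6g}")
    df["enriched"] = df["enriched"].map(lambda b: "true" if b else "false")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
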