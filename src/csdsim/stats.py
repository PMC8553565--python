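"""Exact inference for small success/failure contingency tables.

Slice experiments yield r groups of independent binary outcomes (CSD
induced / not induced).  With a handful of slices per group, asymptotic
chi-square inference is unreliable, so hypotheses about equal success
probability across groups are tested by conditioning on the margins and
enumerating tables exactly: Fisher's exact test for two groups and its
Freeman-Halton generalization for r groups.

All probabilities are accumulated in log space so that p-values on the
1e-14 scale are representable without underflow.  The two-sided p-value
follows the mainstream convention (R ``fisher.test``, scipy): sum the
conditional probabilities of every margin-consistent table whose
probability does not exceed that of the observed table, with a small
relative tolerance when comparing probabilities so that floating-point
ties land inside the rejection set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import exp, lgamma, log
from typing import Iterator, Sequence

__all__ = [
    "ContingencyTable",
    "fisher_exact_2x2",
    "fisher_exact_rx2",
    "pairwise_fisher_bonferroni",
    "hypergeom_log_pmf",
    "load_packaged_tables",
]

#: relative tolerance used when deciding whether a candidate table is
#: "at most as probable" as the observed one (tie inclusion).
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """r groups x (success, failure) counts.

    Parameters
    ----------
    labels
        One label per group.
    successes
        Number of successful outcomes per group.
    totals
        Group sizes; ``successes[i] <= totals[i]``.
    """

    labels: tuple[str, ...]
    successes: tuple[int, ...]
    totals: tuple[int, ...]
    flag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.successes) or len(self.labels) != len(self.totals):
            raise ValueError("labels, successes and totals must have equal length")
        if len(self.labels) < 2:
            raise ValueError("a contingency table needs at least 2 groups")
        for s, n in zip(self.successes, self.totals):
            if n <= 0:
                raise ValueError("group totals must be positive")
            if s < 0 or s > n:
                raise ValueError(f"successes {s} outside [0, {n}]")

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[tuple[int, int]],
        labels: Sequence[str] | None = None,
        flag: str | None = None,
    ) -> "ContingencyTable":
        """Build from ``(successes, total)`` pairs."""
        labels = tuple(labels) if labels is not None else tuple(
            f"group{i}" for i in range(len(counts))
        )
        return cls(
            labels=labels,
            successes=tuple(s for s, _ in counts),
            totals=tuple(n for _, n in counts),
            flag=flag,
        )

    @property
    def failures(self) -> tuple[int, ...]:
        return tuple(n - s for s, n in zip(self.successes, self.totals))

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        cells = ", ".join(
            f"{lab}: {s}/{n}" for lab, s, n in zip(self.labels, self.successes, self.totals)
        )
        return f"ContingencyTable({cells})"


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_log_pmf(k: int, n_success: int, n_failure: int, draws: int) -> float:
    """Log pmf of the hypergeometric count ``k`` of successes in ``draws``
    draws without replacement from ``n_success`` successes and
    ``n_failure`` failures.

    Returns ``-inf`` outside the support.
    """
    if k < 0 or k > draws or k > n_success or draws - k > n_failure:
        return float("-inf")
    return (
        _log_binom(n_success, k)
        + _log_binom(n_failure, draws - k)
        - _log_binom(n_success + n_failure, draws)
    )


def _logsumexp(values: Sequence[float]) -> float:
    m = max(values)
    if m == float("-inf"):
        return m
    return m + log(sum(exp(v - m) for v in values))


def fisher_exact_2x2(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Two-group exact test of equal success probability.

    Conditions on both margins; the first group's success count is then
    hypergeometric.  ``alternative`` may be ``"two-sided"`` (default,
    probability-ordering rule), ``"greater"`` or ``"less"`` (first group's
    success proportion vs the second's).
    """
    if table.n_groups != 2:
        raise ValueError("fisher_exact_2x2 requires exactly 2 groups")
    s1, s2 = table.successes
    n1, n2 = table.totals
    m_succ = s1 + s2                      # success-column margin
    m_fail = (n1 - s1) + (n2 - s2)
    if m_succ == 0 or m_fail == 0:
        return 1.0                        # degenerate: only one outcome observed
    lo = max(0, m_succ - n2)
    hi = min(n1, m_succ)
    log_obs = hypergeom_log_pmf(s1, m_succ, m_fail, n1)
    if alternative == "greater":
        terms = [hypergeom_log_pmf(k, m_succ, m_fail, n1) for k in range(s1, hi + 1)]
    elif alternative == "less":
        terms = [hypergeom_log_pmf(k, m_succ, m_fail, n1) for k in range(lo, s1 + 1)]
    elif alternative == "two-sided":
        cutoff = log_obs + log(1.0 + _TIE_RTOL)
        terms = [
            lp
            for k in range(lo, hi + 1)
            if (lp := hypergeom_log_pmf(k, m_succ, m_fail, n1)) <= cutoff
        ]
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, exp(_logsumexp(terms)))


def _iter_success_columns(
    totals: Sequence[int], remaining: int
) -> Iterator[tuple[int, ...]]:
    """All ways to place ``remaining`` successes into groups with caps."""
    if len(totals) == 1:
        if 0 <= remaining <= totals[0]:
            yield (remaining,)
        return
    tail_cap = sum(totals[1:])
    lo = max(0, remaining - tail_cap)
    hi = min(totals[0], remaining)
    for k in range(lo, hi + 1):
        for rest in _iter_success_columns(totals[1:], remaining - k):
            yield (k,) + rest


def _log_table_prob(successes: Sequence[int], totals: Sequence[int]) -> float:
    """Log conditional probability of an r x 2 table given all margins.

    P = [prod_i C(n_i, s_i)] / C(N, S) with N = sum n_i, S = sum s_i.
    """
    n_total = sum(totals)
    s_total = sum(successes)
    lp = -_log_binom(n_total, s_total)
    for s, n in zip(successes, totals):
        lp += _log_binom(n, s)
    return lp


def fisher_exact_rx2(table: ContingencyTable, max_tables: int = 2_000_000) -> float:
    """Freeman-Halton exact test for r groups of binary outcomes.

    Enumerates every r x 2 table with the observed margins and sums the
    conditional probabilities of those no more probable than the observed
    table.  Reduces exactly to :func:`fisher_exact_2x2` for two groups.

    Raises
    ------
    ResourceWarning
        If the enumeration would exceed ``max_tables`` tables; the test
        never falls back to a silent approximation.
    """
    totals = table.totals
    s_total = sum(table.successes)
    f_total = sum(table.failures)
    if s_total == 0 or f_total == 0:
        return 1.0
    # cheap upper bound on enumeration size before committing
    bound = 1
    for n in totals[:-1]:
        bound *= min(n, s_total) + 1
        if bound > max_tables:
            raise ResourceWarning(
                f"enumeration bound {bound} exceeds budget {max_tables}"
            )
    log_obs = _log_table_prob(table.successes, totals)
    cutoff = log_obs + log(1.0 + _TIE_RTOL)
    terms = []
    count = 0
    for col in _iter_success_columns(totals, s_total):
        count += 1
        if count > max_tables:
            raise ResourceWarning(f"enumeration exceeded budget {max_tables}")
        lp = _log_table_prob(col, totals)
        if lp <= cutoff:
            terms.append(lp)
    return min(1.0, exp(_logsumexp(terms)))


def pairwise_fisher_bonferroni(
    table: ContingencyTable, reference: str | int = 0
) -> dict[str, dict[str, float]]:
    """Pairwise 2x2 exact tests of every group against a reference group,
    Bonferroni-adjusted for the number of comparisons.

    Returns a mapping ``other_label -> {"p_raw": ..., "p_adjusted": ...}``
    with adjusted values capped at 1.
    """
    if isinstance(reference, str):
        ref_idx = table.labels.index(reference)
    else:
        ref_idx = int(reference)
    others = [i for i in range(table.n_groups) if i != ref_idx]
    m = len(others)
    out: dict[str, dict[str, float]] = {}
    for i in others:
        sub = ContingencyTable(
            labels=(table.labels[ref_idx], table.labels[i]),
            successes=(table.successes[ref_idx], table.successes[i]),
            totals=(table.totals[ref_idx], table.totals[i]),
        )
        p = fisher_exact_2x2(sub)
        out[table.labels[i]] = {"p_raw": p, "p_adjusted": min(1.0, m * p)}
    return out


def load_packaged_tables() -> dict[str, ContingencyTable]:
    """The success/failure tables printed in the source study's figure
    legends, keyed by figure panel."""
    text = resources.files("csdsim").joinpath("data/contingency_tables.json").read_text()
    raw = json.loads(text)
    out = {}
    for key, entry in raw.items():
        out[key] = ContingencyTable.from_counts(
            counts=[tuple(c) for c in entry["counts"]],
            labels=entry["labels"],
            flag=entry.get("flag"),
        )
    return out
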