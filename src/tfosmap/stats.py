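"""Significance tests for the conservation analyses.

The null model throughout: ``n`` features positioned at random on a
genome of length ``L`` hit a region of coverage ``C`` (success = an
overlap of at least 1 bp) as a Binomial(n, C/L).  Around it sit the
paired signed-rank test on per-TF FunctCons:SeqCons ratios, a one-sided
rank-sum comparison of binding signals with Bonferroni control, and the
exaptation test: new TFos arise over existing (repurposed) TFos more
often than the genome-wide FunctActive coverage would predict, i.e.
FA/nFC >= M/L is rejected under the binomial null.

All binomial p-values and confidence intervals are exact
(Clopper-Pearson); the rank tests use exact enumeration whenever the
sample permits (no ties, moderate n) and the usual normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class BinomialTestInputs:
    """Inputs of the genomic binomial overlap test.

    L: genome (or universe) length in bases; C: coverage of the success
    region in bases; n: number of features; successes: features
    overlapping the success region by >= 1 bp.
    """

    L: int
    C: int
    n: int
    successes: int

    def __post_init__(self) -> None:
        if not 0 <= self.C <= self.L:
            raise ValueError(f"need 0 <= C <= L, got C={self.C}, L={self.L}")
        if not 0 <= self.successes <= self.n:
            raise ValueError(
                f"need 0 <= successes <= n, got {self.successes}/{self.n}")


@dataclass(frozen=True)
class ExaptationInputs:
    """FA: FunctActive count; nFCo: non-FunctCons count; Mo: coverage in
    bases of (mapped other-genome SeqCons) union (FunctActive here);
    L: genome length."""

    FA: int
    nFCo: int
    Mo: int
    L: int

    def __post_init__(self) -> None:
        if self.FA > self.nFCo:
            raise ValueError(f"FA={self.FA} exceeds nFCo={self.nFCo}")
        if self.Mo > self.L:
            raise ValueError(f"Mo={self.Mo} exceeds L={self.L}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    expected: float
    alternative: str
    n: int = 0
    significant: bool | None = None
    untestable: bool = False
    warning: str | None = None


def binomial_conservation_test(
    inp: BinomialTestInputs,
    conf: float = 0.99,
    alternative: str = "greater",
) -> TestResult:
    """Exact binomial test of feature-overlap enrichment.

    The expected success probability is C/L; the confidence interval on
    successes/n is Clopper-Pearson at level ``conf``.
    """
    if inp.n == 0:
        raise ValueError("n = 0: no features to test")
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0,1), got {conf}")
    p0 = inp.C / inp.L if inp.L else 0.0
    warning = None
    if inp.C == 0 and inp.successes > 0:
        warning = "C = 0 but successes > 0: success region cannot be hit by chance"
    res = sps.binomtest(inp.successes, inp.n, p0, alternative=alternative)
    ci = res.proportion_ci(confidence_level=conf, method="exact")
    return TestResult(
        statistic=inp.successes / inp.n,
        p_value=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        expected=p0,
        alternative=alternative,
        n=inp.n,
        warning=warning,
    )


def paired_wilcoxon_ratio_test(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon signed-rank test on matched per-TF category ratios.

    Each entry is one TF's FunctCons:SeqCons ratio in one species; the
    pairing is the TF.  Zero differences are dropped (Wilcoxon
    convention); if every difference is zero the test degenerates and a
    p-value of 1 is returned with a warning.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("ratio vectors must be equal-length and non-empty "
                         "(no common TFs?)")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, ci_low=0.0, ci_high=0.0,
                          expected=0.0, alternative=alternative, n=0,
                          warning="all paired differences are zero")
    if nz.size <= 25:
        stat, p = _signed_rank_exact(nz, alternative)
    else:
        stat, p = sps.wilcoxon(nz, zero_method="wilcox",
                               alternative=alternative, method="approx")
        if alternative == "two-sided":
            # report W+ uniformly, not scipy's min(T+, T-)
            ranks = sps.rankdata(np.abs(nz))
            stat = float(ranks[nz > 0].sum())
    return TestResult(statistic=float(stat), p_value=float(p),
                      ci_low=float("nan"), ci_high=float("nan"),
                      expected=nz.size * (nz.size + 1) / 4,
                      alternative=alternative, n=int(nz.size))


def _signed_rank_exact(d: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact signed-rank test by convolving the sign-flip distribution.

    Uses midranks, so it remains exact under tied magnitudes (the
    doubled ranks are integers).  The statistic is W+, the rank sum of
    the positive differences.
    """
    ranks = sps.rankdata(np.abs(d))
    doubled = np.rint(2 * ranks).astype(int)
    w2_obs = int(np.rint(2 * ranks[d > 0].sum()))
    counts = np.zeros(doubled.sum() + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else 2 * counts
    total = 2.0 ** len(doubled)
    p_greater = counts[w2_obs:].sum() / total
    p_less = counts[: w2_obs + 1].sum() / total
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(ranks[d > 0].sum()), float(p)


def signal_comparison(
    conserved_signals: Sequence[float],
    seqcons_signals: Sequence[float],
    m: int = 1,
    alpha: float = 0.01,
) -> TestResult:
    """One-sided Mann-Whitney U: are binding signals on FunctCons or
    FunctActive elements higher than on SeqCons elements of the same
    assay?

    ``m`` is the number of assay-level tests in the family; the result
    is flagged significant when p < alpha/m (Bonferroni).  The ratio of
    group means is reported as ``expected`` alongside.
    """
    x = np.asarray(conserved_signals, dtype=float)
    y = np.asarray(seqcons_signals, dtype=float)
    if x.size == 0 or y.size == 0:
        return TestResult(statistic=float("nan"), p_value=float("nan"),
                          ci_low=float("nan"), ci_high=float("nan"),
                          expected=float("nan"), alternative="greater",
                          n=int(x.size + y.size), untestable=True,
                          warning="empty signal group")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 25 and not has_ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    mean_ratio = float(np.mean(x) / np.mean(y)) if np.mean(y) != 0 else float("inf")
    return TestResult(statistic=float(stat), p_value=float(p),
                      ci_low=float("nan"), ci_high=float("nan"),
                      expected=mean_ratio, alternative="greater",
                      n=int(x.size + y.size),
                      significant=bool(p < alpha / m))


def _union_coverage(intervals) -> int:
    """Total bases covered by a collection of (chrom, start, end)."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def exaptation_inputs(
    classified_here: Sequence["ClassifiedTFos"],
    classified_other: Sequence["ClassifiedTFos"],
    genome_length: int,
) -> ExaptationInputs:
    """Assemble the exaptation-test inputs for one genome.

    ``classified_here`` are this genome's TFos; ``classified_other`` the
    other genome's (whose mapped SeqCons elements land back on this
    genome).  Mo is the union coverage, on this genome, of the mapped
    SeqCons elements of the other genome together with this genome's
    FunctActive elements.
    """
    from tfosmap.classify import Category
    from tfosmap.mapper import MapStatus

    fa = sum(1 for c in classified_here
             if c.category is Category.FUNCT_ACTIVE)
    n_fco = sum(1 for c in classified_here
                if c.category is not Category.FUNCT_CONS)
    spans = [(c.peak.interval.chrom, c.peak.interval.start,
              c.peak.interval.end)
             for c in classified_here if c.category is Category.FUNCT_ACTIVE]
    spans += [(c.mapped.target.chrom, c.mapped.target.start,
               c.mapped.target.end)
              for c in classified_other
              if c.category is Category.SEQ_CONS
              and c.mapped.status is MapStatus.MAPPED]
    mo = _union_coverage(spans) if spans else 0
    return ExaptationInputs(FA=fa, nFCo=n_fco, Mo=mo, L=genome_length)


def conservation_report(
    classified: Sequence["ClassifiedTFos"],
    one_map,
    compendium,
    which: str = "A",
    conf: float = 0.99,
) -> "pandas.DataFrame":
    """Sequence- and activity-level binomial conservation tests for one
    species' classified TFos.

    Sequence level: n features of this genome (length L) hitting the
    one-to-one mappable sequence (coverage C) by >= 1 bp.  Activity
    level: n mapped features landing (on the mappable portion of the
    other genome, length L) on the other species' peak compendium
    (mappable coverage C).
    """
    import pandas as pd

    from tfosmap.classify import Category
    from tfosmap.mapper import MapStatus

    L = sum(one_map.sizes(which).values())
    C = one_map.mapped_bases
    n = len(classified)
    mapped = [c for c in classified if c.mapped.status is MapStatus.MAPPED]
    seq = binomial_conservation_test(
        BinomialTestInputs(L=L, C=C, n=n, successes=len(mapped)), conf=conf,
        alternative="two-sided")

    other = "B" if which == "A" else "A"
    trees = one_map.tree(other)
    comp_cov = _union_coverage(
        (p.interval.chrom, max(p.interval.start, iv.begin),
         min(p.interval.end, iv.end))
        for peaks in compendium.values() for p in peaks
        if p.interval.chrom in trees
        for iv in trees[p.interval.chrom].overlap(p.interval.start,
                                                  p.interval.end))
    successes = sum(1 for c in mapped
                    if c.category in (Category.FUNCT_CONS,
                                      Category.FUNCT_ACTIVE))
    funct = binomial_conservation_test(
        BinomialTestInputs(L=C, C=comp_cov, n=len(mapped),
                           successes=successes), conf=conf,
        alternative="two-sided")

    rows = []
    for label, inp, res in (
            ("sequence_conservation", (L, C, n, len(mapped)), seq),
            ("activity_conservation", (C, comp_cov, len(mapped), successes),
             funct)):
        rows.append({
            "test": label, "L": inp[0], "C": inp[1], "n": inp[2],
            "successes": inp[3], "observed": res.statistic,
            "expected": res.expected, "p_value": res.p_value,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "conf": conf,
        })
    return pd.DataFrame(rows)


def exaptation_test(inp: ExaptationInputs, conf: float = 0.99) -> TestResult:
    """Do new TFos preferentially arise over existing (repurposed)
    TFos?

    One-sided exact binomial test of FA successes in nFCo trials against
    the null probability Mo/L; reports the one-sided lower confidence
    bound on FA/nFCo, i.e. an interval of the form (low, 1.000).
    """
    if inp.nFCo == 0:
        raise ValueError("nFCo = 0: no non-FunctCons elements")
    p0 = inp.Mo / inp.L if inp.L else 0.0
    res = sps.binomtest(inp.FA, inp.nFCo, p0, alternative="greater")
    # one-sided exact (Clopper-Pearson) lower bound at level `conf`
    if inp.FA == 0:
        low = 0.0
    else:
        low = float(sps.beta.ppf(1 - conf, inp.FA, inp.nFCo - inp.FA + 1))
    return TestResult(statistic=inp.FA / inp.nFCo, p_value=float(res.pvalue),
                      ci_low=low, ci_high=1.0, expected=p0,
                      alternative="greater", n=inp.nFCo)
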