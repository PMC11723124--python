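"""Ploidy inference from the allele balance of heterozygous calls.

At a heterozygous site in a sample of ploidy ``m`` carrying ``d`` copies of
the alternate allele, the fraction of sequencing reads supporting the
alternate allele is binomially distributed around ``d/m``: diploid
heterozygotes peak at 1/2, triploids at 1/3 and 2/3, tetraploids at 1/4,
1/2 and 3/4.  Each candidate ploidy is therefore fit as a binomial mixture
with *fixed* component means ``mu_d = d/m (1 - e) + (1 - d/m) e`` (``e`` =
per-read miscall rate); only the mixture weights are free, estimated by EM.
Candidates are compared by BIC and the minimizer is returned.

Because the diploid and tetraploid models share the 1/2 component, an
over-parameterized tetraploid fit can win on noise alone; the tetraploid
model is accepted over the diploid one only when its side components (1/4 +
3/4) carry at least ``min_side_weight`` total weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .vcfio import MISSING, VariantMatrix

logger = logging.getLogger(__name__)

#: ploidy value reported when too few usable heterozygous sites exist
UNDETERMINED = 0


@dataclass
class MixtureFit:
    """One fixed-mean binomial mixture fit for a single candidate ploidy."""

    ploidy: int
    log_likelihood: float
    bic: float
    weights: np.ndarray  # per component d = 1..ploidy-1
    component_means: np.ndarray
    n_sites: int
    converged: bool = True

    @property
    def peak_summary(self) -> list[tuple[float, float]]:
        """(expected allele-balance ratio, mixture weight) per component."""
        m = self.ploidy
        return [
            (d / m, float(w)) for d, w in zip(range(1, m), self.weights)
        ]


@dataclass
class PloidyCall:
    """Inferred ploidy for one sample with per-candidate model scores."""

    sample: str
    ploidy: int  # UNDETERMINED (0) when not callable
    model_scores: dict[int, float] = field(default_factory=dict)  # ploidy -> BIC
    n_het_sites: int = 0
    peak_summary: list[tuple[float, float]] = field(default_factory=list)
    confidence: float = float("nan")  # BIC gap best vs runner-up
    low_confidence: bool = False
    fits: dict[int, MixtureFit] = field(default_factory=dict)


def het_allele_fractions(
    vm: VariantMatrix,
    sample: str,
    min_dp: int = 10,
    trim: tuple[float, float] = (0.1, 0.9),
    return_depths: bool = False,
):
    """Alt-read fractions at the sample's heterozygous calls.

    A call qualifies when it is non-missing, heterozygous
    (``0 < dosage < call_ploidy``), has known allele depths and
    ``ref + alt >= min_dp``.  Fractions outside ``trim`` are discarded as
    sequencing-error leakage from homozygous genotypes.

    Returns the fraction array, or ``(fractions, total_depths)`` when
    ``return_depths`` is set.  Empty output means no qualifying site.
    """
    j = vm.sample_index(sample)
    dos = vm.dosage[:, j]
    pl = vm.call_ploidy[:, j]
    ar = vm.ad_ref[:, j]
    aa = vm.ad_alt[:, j]
    ok = (
        (dos != MISSING)
        & (dos > 0)
        & (dos < pl)
        & (ar != MISSING)
        & (aa != MISSING)
        & (ar + aa >= min_dp)
    )
    tot = (ar[ok] + aa[ok]).astype(float)
    frac = aa[ok].astype(float) / tot
    lo, hi = trim
    keep = (frac >= lo) & (frac <= hi)
    frac, tot = frac[keep], tot[keep]
    if return_depths:
        return frac, tot
    return frac


def _binom_logpmf_matrix(alt: np.ndarray, tot: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(n_sites, n_components) binomial log pmf with fixed success probs."""
    alt = alt[:, None]
    tot = tot[:, None]
    p = means[None, :]
    return (
        gammaln(tot + 1)
        - gammaln(alt + 1)
        - gammaln(tot - alt + 1)
        + alt * np.log(p)
        + (tot - alt) * np.log1p(-p)
    )


def component_means(ploidy: int, error_rate: float) -> np.ndarray:
    """Error-adjusted expected alt fractions d/ploidy for d = 1..ploidy-1."""
    d = np.arange(1, ploidy)
    ratio = d / ploidy
    return ratio * (1 - error_rate) + (1 - ratio) * error_rate


def fit_ploidy_model(
    fractions: np.ndarray,
    total_depths: np.ndarray,
    ploidy: int,
    error_rate: float = 0.01,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> MixtureFit:
    """Fit the fixed-mean binomial mixture for one candidate ploidy.

    Only the component weights are free; they are estimated by EM to a
    relative log-likelihood tolerance of ``rtol``.  The alternate read
    count per site is reconstructed as ``round(fraction * depth)``.

    BIC = -2 logL + (ploidy - 2) ln(n): a model with ``m - 1`` components
    has ``m - 2`` free weights.
    """
    fractions = np.asarray(fractions, dtype=float)
    total_depths = np.asarray(total_depths, dtype=float)
    if fractions.size == 0:
        raise ValueError("no heterozygous sites to fit")
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    n = fractions.size
    alt = np.rint(fractions * total_depths)
    means = component_means(ploidy, error_rate)
    logpmf = _binom_logpmf_matrix(alt, total_depths, means)
    k = means.size

    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        joint = logpmf + np.log(w)[None, :]
        site_ll = logsumexp(joint, axis=1)
        ll = float(site_ll.sum())
        if k == 1:
            converged = True
            break
        resp = np.exp(joint - site_ll[:, None])
        w = resp.mean(axis=0)
        w = np.clip(w, 1e-12, None)
        w /= w.sum()
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= rtol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    else:
        logger.warning("EM did not converge for ploidy %d after %d iterations", ploidy, max_iter)
    # final log-likelihood at the returned weights
    ll = float(logsumexp(logpmf + np.log(w)[None, :], axis=1).sum())
    bic = -2.0 * ll + (ploidy - 2) * np.log(n)
    return MixtureFit(
        ploidy=ploidy,
        log_likelihood=ll,
        bic=float(bic),
        weights=w,
        component_means=means,
        n_sites=n,
        converged=converged,
    )


def call_ploidy(
    vm: VariantMatrix,
    sample: str,
    candidates: set[int] = frozenset({2, 3, 4}),
    min_het_sites: int = 200,
    min_dp: int = 10,
    error_rate: float = 0.01,
    min_side_weight: float = 0.1,
    min_bic_gap: float = 2.0,
) -> PloidyCall:
    """Call one sample's ploidy as the BIC-minimizing mixture model.

    The tetraploid model is accepted over the diploid one only when its
    1/4 + 3/4 components carry total weight >= ``min_side_weight``
    (over-parameterization guard).  The call is flagged low-confidence when
    the best-vs-second BIC gap is below ``min_bic_gap`` or fewer than
    ``min_het_sites`` sites were usable; with fewer sites than the minimum
    the ploidy is reported :data:`UNDETERMINED`.
    """
    if not candidates:
        raise ValueError("candidate ploidy set is empty")
    cands = sorted(candidates)
    if min(cands) < 2:
        raise ValueError("candidate ploidies must be >= 2")
    frac, tot = het_allele_fractions(vm, sample, min_dp=min_dp, return_depths=True)
    n = int(frac.size)
    if n < min_het_sites:
        return PloidyCall(
            sample=sample, ploidy=UNDETERMINED, n_het_sites=n, low_confidence=True
        )
    fits = {
        m: fit_ploidy_model(frac, tot, m, error_rate=error_rate) for m in cands
    }
    scores = {m: fits[m].bic for m in cands}
    order = sorted(cands, key=lambda m: scores[m])
    best = order[0]
    if best == 4 and 2 in scores:
        side = fits[4].weights[[0, 2]].sum()  # 1/4 and 3/4 components
        if side < min_side_weight:
            order = [m for m in order if m != 4]
            best = order[0]
    gap = scores[order[1]] - scores[order[0]] if len(order) > 1 else float("inf")
    fit = fits[best]
    return PloidyCall(
        sample=sample,
        ploidy=best,
        model_scores=scores,
        n_het_sites=n,
        peak_summary=fit.peak_summary,
        confidence=float(gap),
        low_confidence=bool(gap < min_bic_gap),
        fits=fits,
    )


def call_ploidy_all(vm: VariantMatrix, **kwargs) -> pd.DataFrame:
    """Call ploidy for every sample; one row per sample.

    Columns: sample, ploidy (0 = undetermined), n_het_sites, confidence,
    low_confidence and one ``bic_<m>`` column per candidate.  Deterministic
    given the matrix and parameters (EM has a fixed deterministic start).
    """
    calls = [call_ploidy(vm, s, **kwargs) for s in vm.samples]
    cands = sorted(kwargs.get("candidates", {2, 3, 4}))
    rows = []
    for c in calls:
        row = {
            "sample": c.sample,
            "ploidy": c.ploidy,
            "n_het_sites": c.n_het_sites,
            "confidence": c.confidence,
            "low_confidence": c.low_confidence,
        }
        for m in cands:
            row[f"bic_{m}"] = c.model_scores.get(m, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
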