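"""SNP-panel purity estimation for sorted cell pools.

A sorted pool is modelled as a two-population DNA mixture: a fraction ``p``
of target cells with known genotype dosages ``g_t`` and ``1 - p`` background
cells with dosages ``g_b`` (dosage = expected alternate-allele fraction of a
genotype: 0, 0.5 or 1 for hom-ref, het, hom-alt; copy-neutral, equal
ploidy).  At an informative variant (``g_t != g_b``) the expected
alternate-allele fraction is

    f_i(p) = p * g_t_i + (1 - p) * g_b_i

and observed sequencing counts ``alt_i ~ Binomial(depth_i, f_i(p))``.  The
pool purity is the binomial maximum-likelihood estimate of ``p`` over all
informative variants, with a Wald CI from the observed Fisher information.
A weighted-least-squares estimator is provided for depth-free allele
fraction inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

__all__ = [
    "Variant",
    "GenotypePanel",
    "AlleleCounts",
    "PurityEstimate",
    "EnrichmentReport",
    "expected_allele_fraction",
    "estimate_purity",
    "estimate_purity_wls",
    "enrichment_report",
]

_ALLOWED_DOSAGES = (0.0, 0.5, 1.0)


class Variant(NamedTuple):
    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


def _check_dosages(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isin(arr, _ALLOWED_DOSAGES)):
        bad = sorted(set(arr[~np.isin(arr, _ALLOWED_DOSAGES)]))
        raise ValueError(f"{name} dosages outside {{0, 0.5, 1}}: {bad}")
    return arr


@dataclass(frozen=True)
class GenotypePanel:
    """Known target/background genotype dosages at a set of biallelic SNVs."""

    variants: tuple[Variant, ...]
    target_dosage: np.ndarray
    background_dosage: np.ndarray
    n_skipped: int = 0  # records dropped during parsing (multiallelic etc.)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        g_t = _check_dosages(self.target_dosage, "target")
        g_b = _check_dosages(self.background_dosage, "background")
        if len(g_t) != len(self.variants) or len(g_b) != len(self.variants):
            raise ValueError("dosage arrays must align with variants")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        object.__setattr__(self, "target_dosage", g_t)
        object.__setattr__(self, "background_dosage", g_b)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.variants)

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask of variants where target and background differ."""
        return self.target_dosage != self.background_dosage

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class AlleleCounts:
    """Observed ref/alt read counts aligned 1:1 with a panel."""

    variant_ids: tuple[str, ...]
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        ref = np.asarray(self.ref_count, dtype=np.int64)
        alt = np.asarray(self.alt_count, dtype=np.int64)
        if ref.shape != alt.shape or ref.shape[0] != len(self.variant_ids):
            raise ValueError("count arrays must align with variant ids")
        if np.any(ref < 0) or np.any(alt < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "ref_count", ref)
        object.__setattr__(self, "alt_count", alt)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> np.ndarray:
        """alt / depth; NaN where depth is zero."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt_count / np.where(d > 0, d, 1.0), np.nan)


@dataclass(frozen=True)
class PurityEstimate:
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_informative: int
    residuals: np.ndarray  # observed - expected alt fraction, informative variants
    clamped: bool = False
    method: str = "binomial_mle"

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_informative": self.n_informative,
            "clamped": self.clamped,
            "method": self.method,
        }


def expected_allele_fraction(p, g_t, g_b):
    """Mixture alternate-allele fraction ``p * g_t + (1 - p) * g_b``.

    Accepts scalars or aligned arrays for the dosages.
    """
    g_t = _check_dosages(np.asarray(g_t, float), "target")
    g_b = _check_dosages(np.asarray(g_b, float), "background")
    p = np.asarray(p, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    out = p * g_t + (1.0 - p) * g_b
    return float(out) if out.ndim == 0 else out


def _align(panel: GenotypePanel, counts: AlleleCounts):
    if counts.variant_ids != panel.variant_ids:
        idx = {vid: i for i, vid in enumerate(counts.variant_ids)}
        try:
            order = [idx[vid] for vid in panel.variant_ids]
        except KeyError as e:
            raise ValueError(f"counts missing panel variant {e.args[0]!r}") from None
        return counts.alt_count[order], counts.ref_count[order]
    return counts.alt_count, counts.ref_count


def estimate_purity(
    panel: GenotypePanel, counts: AlleleCounts, conf_level: float = 0.95
) -> PurityEstimate:
    """Binomial MLE of the target fraction over informative variants.

    Maximises ``sum_i alt_i log f_i(p) + ref_i log(1 - f_i(p))`` over
    ``p`` in [0, 1] with bounded scalar search followed by a Newton polish on
    the score function; SE from observed Fisher information, Wald CI
    truncated to [0, 1].
    """
    alt, ref = _align(panel, counts)
    mask = panel.informative & (alt + ref > 0)
    if not mask.any():
        raise ValueError("no informative variants with non-zero depth")
    alt = alt[mask].astype(float)
    ref = ref[mask].astype(float)
    g_t = panel.target_dosage[mask]
    g_b = panel.background_dosage[mask]
    delta = g_t - g_b

    def frac(p: float) -> np.ndarray:
        return np.clip(g_b + p * delta, 1e-12, 1.0 - 1e-12)

    def nll(p: float) -> float:
        f = frac(p)
        return -float(np.sum(xlogy(alt, f) + xlogy(ref, 1.0 - f)))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    p_hat = float(res.x)

    def score(p: float) -> float:
        f = frac(p)
        return float(np.sum(delta * (alt / f - ref / (1.0 - f))))

    def neg_info(p: float) -> float:  # second derivative of the log-likelihood
        f = frac(p)
        return -float(np.sum(delta**2 * (alt / f**2 + ref / (1.0 - f) ** 2)))

    # Newton polish so closed-form cases come out exact
    for _ in range(8):
        d2 = neg_info(p_hat)
        if d2 >= 0:
            break
        step = score(p_hat) / d2
        p_new = min(1.0, max(0.0, p_hat - step))
        if p_new == p_hat:
            break
        if nll(p_new) <= nll(p_hat) + 1e-12:
            p_hat = p_new
        else:
            break

    clamped = False
    if p_hat < 0.0 or p_hat > 1.0:  # defensive; search is bounded
        p_hat = min(1.0, max(0.0, p_hat))
        clamped = True
    # boundary solutions where the score pushes outward are clamped MLEs
    if (p_hat == 0.0 and score(0.0) < 0) or (p_hat == 1.0 and score(1.0) > 0):
        clamped = True

    info = -neg_info(p_hat)
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf_level / 2.0)
    ci_low = max(0.0, p_hat - z * se) if np.isfinite(se) else 0.0
    ci_high = min(1.0, p_hat + z * se) if np.isfinite(se) else 1.0
    residuals = alt / (alt + ref) - (g_b + p_hat * delta)
    return PurityEstimate(
        p_hat=p_hat,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_informative=int(mask.sum()),
        residuals=residuals,
        clamped=clamped,
    )


def estimate_purity_wls(
    panel: GenotypePanel,
    alt_fractions: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> PurityEstimate:
    """Weighted-least-squares fallback for depth-free allele fractions.

    Solves ``min_p sum_i w_i (f_i - g_b_i - p (g_t_i - g_b_i))^2`` in closed
    form; clamped to [0, 1].  SE assumes homoscedastic residuals.
    """
    f = np.asarray(alt_fractions, dtype=float)
    if f.shape[0] != len(panel):
        raise ValueError("alt_fractions must align with the panel")
    mask = panel.informative & np.isfinite(f)
    if not mask.any():
        raise ValueError("no informative variants with finite fractions")
    w = np.ones(mask.sum()) if weights is None else np.asarray(weights, float)[mask]
    f = f[mask]
    delta = (panel.target_dosage - panel.background_dosage)[mask]
    y = f - panel.background_dosage[mask]
    denom = float(np.sum(w * delta**2))
    p_raw = float(np.sum(w * delta * y) / denom)
    p_hat = min(1.0, max(0.0, p_raw))
    resid = y - p_hat * delta
    dof = max(1, mask.sum() - 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    se = math.sqrt(sigma2 / denom)
    return PurityEstimate(
        p_hat=p_hat,
        se=se,
        ci_low=max(0.0, p_hat - 1.959963984540054 * se),
        ci_high=min(1.0, p_hat + 1.959963984540054 * se),
        n_informative=int(mask.sum()),
        residuals=resid,
        clamped=p_hat != p_raw,
        method="wls",
    )


@dataclass(frozen=True)
class EnrichmentReport:
    fold_enrichment: float
    fold_ci_low: float
    fold_ci_high: float
    pre: PurityEstimate
    post: PurityEstimate

    def to_dict(self) -> dict:
        return {
            "fold_enrichment": self.fold_enrichment,
            "fold_ci_low": self.fold_ci_low,
            "fold_ci_high": self.fold_ci_high,
            "pre": self.pre.to_dict(),
            "post": self.post.to_dict(),
        }


def enrichment_report(pre: PurityEstimate, post: PurityEstimate) -> EnrichmentReport:
    """Fold enrichment ``post.p_hat / pre.p_hat`` with a delta-method CI."""
    if pre.p_hat <= 0:
        raise ValueError("enrichment undefined: pre-sort purity estimate is zero")
    fold = post.p_hat / pre.p_hat
    rel_var = 0.0
    for est in (pre, post):
        if np.isfinite(est.se) and est.p_hat > 0:
            rel_var += (est.se / est.p_hat) ** 2
    se_fold = fold * math.sqrt(rel_var)
    return EnrichmentReport(
        fold_enrichment=fold,
        fold_ci_low=max(0.0, fold - 1.959963984540054 * se_fold),
        fold_ci_high=fold + 1.959963984540054 * se_fold,
        pre=pre,
        post=post,
    )
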