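"""Synthetic generators standing in for the instrument and the trained classifier.

The downstream evaluation and sorting modules only require per-cell softmax
score vectors, embeddings, Poisson arrival streams and SNP allele counts with
the right statistical structure; this module produces all four from seeded
NumPy generators so every experiment is reproducible bit-for-bit.

Score model
-----------
Scores are drawn in logit space: for a cell of true class ``j`` the logit
vector is ``separability * e_j + eps`` with ``eps ~ N(0, logit_scale^2 I)``,
pushed through a softmax.  ``separability`` therefore controls the expected
margin between the true class and the rest: at 0 every class is
exchangeable (mean score 1/K), and as it grows the argmax converges to the
true label and every one-vs-rest ROC AUC increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DEFAULT_QUALITY_CLASSES",
    "ScoreModel",
    "CellRecord",
    "MixtureSpec",
    "sample_score_vectors",
    "sample_cohort",
    "sample_embeddings",
    "sample_allele_counts",
    "circulating_cell_mixture",
]

#: Class names treated as image-quality classes rather than cell types.
DEFAULT_QUALITY_CLASSES = frozenset({"debris", "out_of_focus"})

_SIMPLEX_TOL = 1e-9
_ALLOWED_DOSAGES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class ScoreModel:
    """Class-conditional softmax score generator.

    Parameters
    ----------
    class_names
        Ordered output classes of the virtual classifier (K >= 2).
    separability
        Non-negative margin added to the true class logit.
    logit_scale
        Standard deviation of the Gaussian logit noise.
    """

    class_names: tuple[str, ...]
    separability: float = 4.0
    logit_scale: float = 1.0

    def __post_init__(self) -> None:
        names = tuple(self.class_names)
        object.__setattr__(self, "class_names", names)
        if len(names) < 2:
            raise ValueError("ScoreModel requires at least two classes")
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.logit_scale <= 0:
            raise ValueError("logit_scale must be > 0")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_index(self, label: str) -> int:
        try:
            return self.class_names.index(label)
        except ValueError:
            raise KeyError(
                f"unknown class label {label!r}; known: {list(self.class_names)}"
            ) from None


@dataclass(frozen=True)
class CellRecord:
    """One imaged cell: ground-truth label plus classifier outputs."""

    cell_id: str
    true_label: str
    scores: np.ndarray
    class_names: tuple[str, ...]
    embedding: Optional[np.ndarray] = None
    arrival_time: Optional[float] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 1 or s.shape[0] != len(self.class_names):
            raise ValueError("scores must be a vector aligned with class_names")
        if np.any(s < 0) or abs(float(s.sum()) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"scores for cell {self.cell_id!r} are not on the simplex"
            )
        if self.true_label not in self.class_names:
            raise ValueError(f"true_label {self.true_label!r} not in class_names")
        if self.arrival_time is not None and self.arrival_time < 0:
            raise ValueError("arrival_time must be >= 0")

    def score(self, label: str) -> float:
        return float(self.scores[self.class_names.index(label)])

    @property
    def scores_by_class(self) -> dict[str, float]:
        return dict(zip(self.class_names, map(float, self.scores)))

    @property
    def predicted_label(self) -> str:
        """Argmax class; ties broken by class-name sort order."""
        best = self.scores.max()
        tied = [n for n, s in zip(self.class_names, self.scores) if s == best]
        return min(tied)


@dataclass(frozen=True)
class MixtureSpec:
    """Class proportions of a sample and the designated target class.

    ``pi`` is the target proportion (e.g. 1e-5 for a 1:100,000 spike-in).
    """

    proportions: Mapping[str, float]
    target_class: str

    def __post_init__(self) -> None:
        props = dict(self.proportions)
        object.__setattr__(self, "proportions", props)
        total = sum(props.values())
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"mixture proportions sum to {total!r}, not 1")
        if any(not (0.0 < f <= 1.0) for f in props.values()):
            raise ValueError("every mixture fraction must lie in (0, 1]")
        if self.target_class not in props:
            raise ValueError(
                f"target_class {self.target_class!r} absent from proportions"
            )

    @property
    def pi(self) -> float:
        return float(self.proportions[self.target_class])

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.proportions)


def circulating_cell_mixture(
    target_class: str = "target",
    pi: float = 1e-3,
    background_class: str = "background",
    quality_fractions: Mapping[str, float] | None = None,
) -> MixtureSpec:
    """Mixture preset mirroring the circulating-cell training composition.

    Quality classes default to 39.01% out-of-focus and 6.57% debris; the
    remainder is split between the target (at proportion ``pi`` of the
    evaluable fraction) and the background class.
    """
    if quality_fractions is None:
        quality_fractions = {"out_of_focus": 0.3901, "debris": 0.0657}
    q_total = sum(quality_fractions.values())
    evaluable = 1.0 - q_total
    props = dict(quality_fractions)
    props[target_class] = pi * evaluable
    props[background_class] = (1.0 - pi) * evaluable
    return MixtureSpec(proportions=props, target_class=target_class)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sample_score_vectors(
    model: ScoreModel, label: str, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` softmax score vectors for cells of true class ``label``.

    Deterministic in ``(model, label, n, seed)``.
    """
    j = model.class_index(label)
    if n < 0:
        raise ValueError("n must be >= 0")
    K = model.n_classes
    if n == 0:
        return np.empty((0, K))
    rng = np.random.default_rng(seed)
    logits = rng.normal(0.0, model.logit_scale, size=(n, K))
    logits[:, j] += model.separability
    return _softmax_rows(logits)


def sample_cohort(
    model: ScoreModel,
    mixture: MixtureSpec,
    n: int,
    seed: int,
    cell_rate_per_min: float | None = None,
    embedding_centroids: Mapping[str, Sequence[float]] | None = None,
    embedding_spread: float = 1.0,
    id_prefix: str = "cell",
) -> list[CellRecord]:
    """Draw an i.i.d. cohort from a class mixture.

    Labels are multinomial in ``mixture.proportions``; scores come from the
    score model conditioned on each label.  If ``cell_rate_per_min`` is given,
    arrival times are a homogeneous Poisson-process realisation at that rate.
    If ``embedding_centroids`` is given every cell also gets an embedding.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    for name in mixture.class_names:
        model.class_index(name)  # raises on unknown classes
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    names = list(mixture.class_names)
    probs = np.array([mixture.proportions[c] for c in names])
    label_idx = rng.choice(len(names), size=n, p=probs / probs.sum())
    labels = [names[i] for i in label_idx]

    K = model.n_classes
    logits = rng.normal(0.0, model.logit_scale, size=(n, K))
    cols = np.array([model.class_index(lab) for lab in labels])
    logits[np.arange(n), cols] += model.separability
    scores = _softmax_rows(logits)

    times: Optional[np.ndarray] = None
    if cell_rate_per_min is not None:
        if cell_rate_per_min <= 0:
            raise ValueError("cell_rate_per_min must be > 0")
        lam = cell_rate_per_min / 60.0  # per second
        times = np.cumsum(rng.exponential(1.0 / lam, size=n))

    embeddings: Optional[np.ndarray] = None
    if embedding_centroids is not None:
        embeddings = sample_embeddings(
            embedding_centroids,
            embedding_spread,
            labels,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    width = len(str(max(n - 1, 1)))
    return [
        CellRecord(
            cell_id=f"{id_prefix}{i:0{width}d}",
            true_label=labels[i],
            scores=scores[i],
            class_names=model.class_names,
            embedding=None if embeddings is None else embeddings[i],
            arrival_time=None if times is None else float(times[i]),
        )
        for i in range(n)
    ]


def sample_embeddings(
    centroids: Mapping[str, Sequence[float]],
    spread: float,
    labels: Sequence[str],
    seed: int,
) -> np.ndarray:
    """Isotropic Gaussian embedding clouds around per-class centroids."""
    if spread <= 0:
        raise ValueError("spread must be > 0")
    cents = {k: np.asarray(v, dtype=float) for k, v in centroids.items()}
    dims = {v.shape for v in cents.values()}
    if len(dims) > 1:
        raise ValueError("all centroids must share one dimensionality")
    missing = sorted(set(labels) - set(cents))
    if missing:
        raise KeyError(f"no centroid for labels: {missing}")
    d = next(iter(dims))[0] if cents else 0
    if len(labels) == 0:
        return np.empty((0, d))
    rng = np.random.default_rng(seed)
    mu = np.stack([cents[lab] for lab in labels])
    return mu + rng.normal(0.0, spread, size=mu.shape)


def sample_allele_counts(
    panel,
    purity: float,
    depth: float,
    seed: int,
):
    """Binomial allele counts from a two-population DNA mixture.

    Per variant the alternate-allele fraction is
    ``f_i = purity * g_t_i + (1 - purity) * g_b_i`` and the observed counts
    are ``alt_i ~ Binomial(depth_i, f_i)`` with ``depth_i ~ Poisson(depth)``.

    Returns an :class:`iacsim.genotype.AlleleCounts` aligned to the panel.
    """
    from .genotype import AlleleCounts, expected_allele_fraction

    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    g_t = np.asarray(panel.target_dosage, dtype=float)
    g_b = np.asarray(panel.background_dosage, dtype=float)
    for g in (g_t, g_b):
        if not np.all(np.isin(g, _ALLOWED_DOSAGES)):
            raise ValueError("dosages must be in {0, 0.5, 1}")
    f = expected_allele_fraction(purity, g_t, g_b)
    rng = np.random.default_rng(seed)
    depths = rng.poisson(depth, size=f.shape)
    alt = rng.binomial(depths, f)
    return AlleleCounts(
        variant_ids=tuple(panel.variant_ids),
        ref_count=depths - alt,
        alt_count=alt,
    )
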