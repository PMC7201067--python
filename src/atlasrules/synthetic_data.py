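"""Synthetic single-cell atlas generator with planted marker genes.

Emulates the statistical structure of an 18-tissue mouse cell atlas:
unbalanced tissue classes, a small set of tissue-specific marker genes
per class, a large background of uninformative genes, and dropout-laden
non-negative expression.  Values are drawn on a log-like scale as
``max(0, Normal(mean, noise_sd))`` — a marker gene's mean is shifted up
by ``effect_size`` in its home tissue — and then independently zeroed
with probability ``dropout_rate`` (capture dropout).  Ground truth
(which gene marks which tissue) is returned alongside the dataset so
recovery tests are unambiguous.

The generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import ExpressionDataset

__all__ = [
    "TISSUE_SIZES",
    "table1_sizes",
    "SyntheticSpec",
    "MarkerTruth",
    "generate_dataset",
    "scaled_atlas_spec",
]

# Per-tissue cell counts of the 18-tissue mouse atlas (GSE109774 profile).
TISSUE_SIZES: tuple[tuple[str, int], ...] = (
    ("Bladder", 1638),
    ("Brain microglia", 4762),
    ("Brain neurons", 5799),
    ("Colon", 4149),
    ("Fat", 5862),
    ("Heart", 7115),
    ("Kidney", 865),
    ("Liver", 981),
    ("Lung", 1923),
    ("Mammary", 2663),
    ("Marrow", 5355),
    ("Muscle", 2102),
    ("Pancreas", 1961),
    ("Skin", 2464),
    ("Spleen", 1718),
    ("Thymus", 1580),
    ("Tongue", 1432),
    ("Trachea", 1391),
)


def table1_sizes() -> dict[str, int]:
    """The 18 (tissue, cell count) pairs of the atlas, in index order."""
    return dict(TISSUE_SIZES)


class SpecError(ValueError):
    """Raised when a SyntheticSpec field is invalid."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic atlas.

    ``class_sizes`` defaults to the 18-tissue atlas profile when
    ``n_classes`` is 18.  Total genes = ``n_classes * markers_per_class
    + n_noise_genes``.
    """

    n_classes: int = 18
    class_sizes: tuple[int, ...] | None = None
    markers_per_class: int = 5
    n_noise_genes: int = 400
    effect_size: float = 2.0
    base_mean: float = 1.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.3
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise SpecError("n_classes must be >= 1")
        if self.class_sizes is None:
            if self.n_classes == 18:
                self.class_sizes = tuple(s for _, s in TISSUE_SIZES)
            else:
                raise SpecError("class_sizes required when n_classes != 18")
        self.class_sizes = tuple(int(s) for s in self.class_sizes)
        if len(self.class_sizes) != self.n_classes:
            raise SpecError(
                f"class_sizes has {len(self.class_sizes)} entries for "
                f"{self.n_classes} classes"
            )
        if any(s < 1 for s in self.class_sizes):
            raise SpecError("class_sizes entries must all be >= 1")
        if self.markers_per_class < 1:
            raise SpecError("markers_per_class must be >= 1")
        if self.n_noise_genes < 0:
            raise SpecError("n_noise_genes must be >= 0")
        if self.effect_size < 0:
            raise SpecError("effect_size must be >= 0")
        if self.base_mean <= 0:
            raise SpecError("base_mean must be > 0")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise SpecError("dropout_rate must lie in [0, 1]")
        if self.class_names is None:
            if self.n_classes == 18:
                self.class_names = tuple(t for t, _ in TISSUE_SIZES)
            else:
                self.class_names = tuple(
                    f"class{i}" for i in range(self.n_classes)
                )
        else:
            self.class_names = tuple(str(c) for c in self.class_names)
        if len(self.class_names) != self.n_classes:
            raise SpecError("class_names length must equal n_classes")

    @property
    def n_genes(self) -> int:
        return self.n_classes * self.markers_per_class + self.n_noise_genes

    @property
    def n_cells(self) -> int:
        return int(sum(self.class_sizes))


@dataclass
class MarkerTruth:
    """Ground truth: which planted marker gene belongs to which tissue."""

    marker_to_class: dict[str, str]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_to_class)

    def markers_of(self, tissue: str) -> list[str]:
        return [g for g, t in self.marker_to_class.items() if t == tissue]

    def recovery_fraction(self, selected_gene_ids) -> float:
        """Fraction of planted markers present in ``selected_gene_ids``."""
        sel = set(selected_gene_ids)
        return sum(g in sel for g in self.marker_to_class) / len(
            self.marker_to_class
        )


def _sanitize(name: str) -> str:
    return name.replace(" ", "_")


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, MarkerTruth]:
    """Draw a synthetic atlas and its marker ground truth from ``spec``.

    Each cell of class ``c`` draws its ``markers_per_class`` home markers
    from ``max(0, N(base_mean + effect_size, noise_sd))`` and every other
    gene from ``max(0, N(base_mean, noise_sd))``; each value is then
    zeroed with probability ``dropout_rate``.  Gene columns are shuffled
    so marker positions carry no information.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells, n_genes = spec.n_cells, spec.n_genes
    mpc = spec.markers_per_class

    labels: list[str] = []
    for cname, size in zip(spec.class_names, spec.class_sizes):
        labels.extend([cname] * size)
    y = np.repeat(np.arange(spec.n_classes), spec.class_sizes)

    means = np.full((n_cells, n_genes), spec.base_mean)
    for c in range(spec.n_classes):
        rows = y == c
        means[np.ix_(rows, np.arange(c * mpc, (c + 1) * mpc))] += spec.effect_size

    X = rng.normal(means, spec.noise_sd)
    np.maximum(X, 0.0, out=X)
    if spec.dropout_rate > 0:
        X[rng.random(X.shape) < spec.dropout_rate] = 0.0

    gene_ids = [
        f"{_sanitize(spec.class_names[c])}.mk{j}"
        for c in range(spec.n_classes)
        for j in range(mpc)
    ] + [f"noise{i:05d}" for i in range(spec.n_noise_genes)]
    truth = {
        gene_ids[c * mpc + j]: spec.class_names[c]
        for c in range(spec.n_classes)
        for j in range(mpc)
    }

    perm = rng.permutation(n_genes)
    X = X[:, perm]
    gene_ids = [gene_ids[i] for i in perm]

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    ds = ExpressionDataset(X, gene_ids, cell_ids, labels,
                           list(spec.class_names))
    return ds, MarkerTruth(truth)


def scaled_atlas_spec(scale: float, seed: int, **overrides) -> SyntheticSpec:
    """An 18-tissue spec with class sizes ``ceil(scale * atlas size)``.

    ``scale=1`` reproduces the full atlas profile; keyword overrides are
    forwarded to :class:`SyntheticSpec`.
    """
    if not scale > 0:
        raise SpecError("scale must be > 0")
    sizes = tuple(math.ceil(scale * s) for _, s in TISSUE_SIZES)
    return SyntheticSpec(n_classes=18, class_sizes=sizes, seed=seed,
                         **overrides)


def expected_zero_fraction(spec: SyntheticSpec, marker_in_home: bool = False) -> float:
    """Closed-form P(value == 0) for a background (or home-marker) entry.

    Zeros arise from dropout or from the Gaussian draw being clipped at
    zero: ``p = d + (1 - d) * Phi(-mu / sd)``.
    """
    from scipy.stats import norm

    mu = spec.base_mean + (spec.effect_size if marker_in_home else 0.0)
    p_clip = norm.cdf(-mu / spec.noise_sd)
    return spec.dropout_rate + (1 - spec.dropout_rate) * p_clip
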