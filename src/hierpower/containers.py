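"""Core data containers shared across the package.

Cells are nested within individuals: the individual, not the cell, is the
independent experimental unit. Every container here carries that mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

#: Negative-binomial size cap used when a gene looks Poisson or underdispersed
#: (observed variance <= mean). At this size the NB is numerically Poisson.
SIZE_MAX = 1.0e6
#: Floor applied to trend-predicted NB sizes so the distribution stays proper.
SIZE_MIN = 1.0e-4
#: Inward nudge applied to dropout rates of exactly 0 or 1 before gamma MLE.
RATE_EPS = 1.0e-6


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """A genes x cells non-negative expression matrix with individual labels.

    Values are TPM-like (library-size normalization is assumed upstream).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    individual_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_of_cell = np.asarray(self.individual_of_cell, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        g, c = self.values.shape
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValueError("gene_ids/cell_ids lengths do not match matrix shape")
        if self.individual_of_cell.shape != (c,):
            raise ValueError("individual_of_cell must have one label per cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (missing values are rejected)")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if len(self.individuals) < 1:
            raise ValueError("at least one individual required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def individuals(self) -> list[str]:
        """Distinct individual labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.individual_of_cell:
            seen.setdefault(lab, None)
        return list(seen)

    def cells_of(self, individual: str) -> np.ndarray:
        """Column indices of the cells belonging to one individual."""
        return np.flatnonzero(self.individual_of_cell == individual)

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            individual_of_cell=self.individual_of_cell,
        )


@dataclass
class SimulationModel:
    """Fitted hyper-parameters driving the hierarchical simulator.

    grand_mean_gamma : (shape, rate) of the gamma distribution of per-gene
        grand means (TPM units).
    f1 : (intercept, slope) linear trend mapping a grand mean to the
        inter-individual variance of per-individual means.
    f2 : (a, b) logarithmic trend mapping a mean to the NB size parameter,
        size = a + b * log(mean).
    dropout_gamma : (shape, rate) of the gamma distribution of per-gene
        dropout probabilities; samples are restricted to [0, 1] by
        rejection at simulation time.
    """

    grand_mean_gamma: tuple[float, float]
    f1: tuple[float, float]
    f2: tuple[float, float]
    dropout_gamma: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("grand_mean_gamma", "dropout_gamma"):
            shape, rate = getattr(self, name)
            if not (shape > 0 and rate > 0):
                raise ValueError(f"{name} shape and rate must be positive")

    def inter_individual_variance(self, mu) -> np.ndarray:
        """f1 evaluated at a (non-negative) mean, floored at 0."""
        a, b = self.f1
        return np.maximum(a + b * np.asarray(mu, dtype=float), 0.0)

    def nb_size(self, mu) -> np.ndarray:
        """f2 evaluated at a mean, clipped into [SIZE_MIN, SIZE_MAX].

        Means of 0 get the floor size; they generate all-zero counts anyway.
        """
        mu = np.asarray(mu, dtype=float)
        a, b = self.f2
        with np.errstate(divide="ignore"):
            raw = a + b * np.log(np.where(mu > 0, mu, 1.0))
        return np.clip(raw, SIZE_MIN, SIZE_MAX)

    def to_json(self, path=None) -> str:
        doc = {
            "grand_mean_gamma": list(self.grand_mean_gamma),
            "f1": list(self.f1),
            "f2": list(self.f2),
            "dropout_gamma": list(self.dropout_gamma),
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls(
            grand_mean_gamma=tuple(doc["grand_mean_gamma"]),
            f1=tuple(doc["f1"]),
            f2=tuple(doc["f2"]),
            dropout_gamma=tuple(doc["dropout_gamma"]),
            provenance=doc.get("provenance", {}),
        )


@dataclass
class SimulationDesign:
    """User-facing description of one simulated experiment.

    Binary designs set ``fold_change`` and ``n_per_group``; continuous
    designs set ``rho``, ``n_individuals``, ``phenotype_mean`` and
    ``phenotype_sd``. Exactly one of fold_change / rho must be given.
    """

    n_genes: int = 1
    frac_de: float = 1.0
    n_per_group: Optional[int] = None
    n_individuals: Optional[int] = None
    cells_per_individual: int = 100
    cell_count_mode: str = "fixed"
    fold_change: Optional[float] = None
    rho: Optional[float] = None
    phenotype_mean: float = 0.0
    phenotype_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.fold_change is None) == (self.rho is None):
            raise ValueError("specify exactly one of fold_change (binary) or rho (continuous)")
        if self.fold_change is not None:
            if self.fold_change <= 0:
                raise ValueError("fold_change must be > 0")
            if not self.n_per_group or self.n_per_group < 1:
                raise ValueError("binary designs need n_per_group >= 1")
        else:
            if abs(self.rho) > 1:
                raise ValueError("|rho| must be <= 1")
            if not self.n_individuals or self.n_individuals < 2:
                raise ValueError("continuous designs need n_individuals >= 2")
            if self.phenotype_sd <= 0:
                raise ValueError("phenotype_sd must be > 0")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must lie in [0, 1]")
        if self.n_genes < 1 or self.cells_per_individual < 1:
            raise ValueError("counts must be >= 1")
        if self.cell_count_mode not in ("fixed", "poisson", "negbin"):
            raise ValueError(f"unknown cell_count_mode: {self.cell_count_mode!r}")

    @property
    def kind(self) -> str:
        return "binary" if self.fold_change is not None else "continuous"

    def nullified(self) -> "SimulationDesign":
        """The same design with the effect removed (fold change 1 / rho 0)."""
        kwargs = asdict(self)
        if self.kind == "binary":
            kwargs["fold_change"] = 1.0
        else:
            kwargs["rho"] = 0.0
        return SimulationDesign(**kwargs)


@dataclass
class SimulatedDataset:
    """Simulated counts plus the design truth needed to score a test."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    individual_of_cell: np.ndarray
    individual_ids: list[str]
    phenotype_of_individual: np.ndarray
    de_flags: np.ndarray
    applied_effect: np.ndarray
    kind: str
    design: Optional[SimulationDesign] = None
    #: generative truth, useful for validation: per-gene grand means and the
    #: realized per-(gene, individual) means the counts were drawn from
    grand_means: Optional[np.ndarray] = None
    individual_means: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.individual_of_cell = np.asarray(self.individual_of_cell, dtype=object)
        self.de_flags = np.asarray(self.de_flags, dtype=bool)
        self.applied_effect = np.asarray(self.applied_effect, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def phenotype_of_cell(self) -> np.ndarray:
        """Per-cell phenotype (group code or trait value of the cell's donor)."""
        lookup = {ind: ph for ind, ph in zip(self.individual_ids, self.phenotype_of_individual)}
        return np.array([lookup[i] for i in self.individual_of_cell], dtype=float)

    def to_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(
            values=self.counts,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            individual_of_cell=self.individual_of_cell,
        )
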