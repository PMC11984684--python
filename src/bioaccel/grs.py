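"""Weighted 12-SNP genetic risk score (GRS) and its tertile categories.

GRS = sum_i beta_i * dosage_i over m = 12 heart-failure-associated variants,
where beta_i is the natural log of the per-allele odds ratio and dosage_i the
count (or imputed dosage) of effect alleles in [0, 2].  No allele-frequency
centering or rescaling is applied: the score is a plain weighted sum.

Dosages must already be oriented to the effect allele; the bundled weight
file is a synthetic placeholder for tests and examples.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .acceleration import quantile_categories

N_SNPS = 12
GRS_TERTILE_LABELS = ["low", "intermediate", "high"]


@dataclass
class GRSWeights:
    snps: list[str]
    effect_alleles: list[str]
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        if len(self.snps) != N_SNPS or self.beta.size != N_SNPS:
            raise ValueError(f"exactly {N_SNPS} SNP weights required")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite beta")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GRSWeights":
        return cls(
            snps=df["snp"].tolist(),
            effect_alleles=df["effect_allele"].tolist(),
            beta=df["beta"].to_numpy(float),
        )

    @classmethod
    def from_file(cls, path) -> "GRSWeights":
        return cls.from_table(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def synthetic_default(cls) -> "GRSWeights":
        """The bundled synthetic placeholder weights (for tests/examples)."""
        with resources.files("bioaccel.data").joinpath("grs_weights_synthetic.tsv").open() as fh:
            return cls.from_table(pd.read_csv(fh, sep="\t", comment="#"))


def weighted_grs(dosages, weights: GRSWeights) -> np.ndarray:
    """Sum of beta_i x dosage_i; dosages shape (n, 12) or (12,)."""
    dosages = np.atleast_2d(np.asarray(dosages, float))
    if dosages.shape[1] != N_SNPS:
        raise ValueError(f"expected {N_SNPS} dosage columns, got {dosages.shape[1]}")
    if np.any((dosages < 0) | (dosages > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    scores = dosages @ weights.beta
    return scores if scores.size > 1 else float(scores[0])


def grs_tertiles(scores) -> np.ndarray:
    """Low / intermediate / high genetic-risk categories (sample tertiles)."""
    return quantile_categories(scores, k=3, labels=GRS_TERTILE_LABELS)
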