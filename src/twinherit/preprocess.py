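"""Standardization, covariate residualization, normality transform, and the
twin-pair difference features used by the MZ-vs-DZ classifiers.

Z-scoring is computed over the full cohort before any train/test split,
mirroring the study procedure this pipeline emulates (a known, deliberate
leakage); ``split_safe_scaling`` in the ML stage offers the strict
alternative.  Residualization and the rank-based inverse normal transform are
applied only in the genetic-correlation stage by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_data import Cohort


class PreprocessError(ValueError):
    pass


def zscore(phenotypes: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column-wise standardization to zero mean and unit variance.

    Idempotent up to floating error.  Raises naming the offending measure if
    a column is constant.
    """
    if len(phenotypes) < 2:
        raise PreprocessError("need at least 2 subjects to z-score")
    sd = phenotypes.std(ddof=ddof)
    constant = sd.index[sd == 0.0]
    if len(constant):
        raise PreprocessError(
            f"constant column(s) cannot be z-scored: {list(constant)}"
        )
    return (phenotypes - phenotypes.mean()) / sd


def covariate_design(age: np.ndarray, sex: np.ndarray) -> pd.DataFrame:
    """Design matrix [1, age, sex, age*sex, age^2, age^2*sex]."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    return pd.DataFrame(
        {
            "intercept": np.ones_like(age),
            "age": age,
            "sex": sex,
            "age_x_sex": age * sex,
            "age2": age**2,
            "age2_x_sex": age**2 * sex,
        }
    )


def residualize(phenotypes: pd.DataFrame, age: np.ndarray,
                sex: np.ndarray) -> pd.DataFrame:
    """Least-squares residuals of each measure on the age/sex design.

    Raises listing the collinear columns when the design is rank-deficient
    (e.g. a single-sex cohort makes every sex interaction collinear).
    """
    design = covariate_design(age, sex)
    x = design.to_numpy()
    if len(x) != len(phenotypes):
        raise PreprocessError("covariates must be present for every subject")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # flag columns whose removal does not drop the rank
        redundant = [c for i, c in enumerate(design.columns)
                     if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank]
        raise PreprocessError(f"rank-deficient covariate design; collinear "
                              f"columns: {redundant}")
    beta, *_ = np.linalg.lstsq(x, phenotypes.to_numpy(), rcond=None)
    resid = phenotypes.to_numpy() - x @ beta
    return pd.DataFrame(resid, index=phenotypes.index, columns=phenotypes.columns)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    ``Phi^-1((rank - 3/8) / (n + 1/4))`` with average ranks for ties; strictly
    monotone in the input.  The 3/8 offset is the Blom convention adopted for
    the otherwise unspecified "inverse Gaussian transformation".
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 3:
        raise PreprocessError("inverse normal transform needs >= 3 distinct values")
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - 0.375) / (values.size + 0.25))


def inverse_normal_transform_frame(phenotypes: pd.DataFrame) -> pd.DataFrame:
    out = {c: inverse_normal_transform(phenotypes[c].to_numpy())
           for c in phenotypes.columns}
    return pd.DataFrame(out, index=phenotypes.index)


@dataclass
class PairFeatureSet:
    """Per-pair absolute z-scored difference features with MZ/DZ labels.

    ``features`` is a pair x measure DataFrame of |z(twin1) - z(twin2)|;
    ``labels`` is +1 for MZ pairs and -1 for DZ pairs.
    """

    features: pd.DataFrame
    labels: np.ndarray
    pair_ids: list[str]

    def __post_init__(self) -> None:
        if (self.features.to_numpy() < 0).any():
            raise PreprocessError("pair features must be non-negative")
        if not np.isin(self.labels, (-1, 1)).all():
            raise PreprocessError("labels must be +1 (MZ) or -1 (DZ)")
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.pair_ids):
            raise PreprocessError("features, labels and pair_ids disagree in length")

    @property
    def n_mz(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_dz(self) -> int:
        return int((self.labels == -1).sum())

    def to_tsv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "label", self.labels)
        out.insert(0, "pair_id", self.pair_ids)
        out.to_csv(path, sep="\t", index=False)


def build_pair_features(cohort: Cohort,
                        phenotypes: pd.DataFrame | None = None) -> PairFeatureSet:
    """One feature row per twin pair: elementwise |z(twin1) - z(twin2)|.

    Invariant to within-pair subject order.  ``phenotypes`` overrides the
    cohort matrix (e.g. to classify on factor scores instead of raw measures).
    """
    data = zscore(cohort.phenotypes if phenotypes is None else phenotypes)
    rows, labels, pair_ids = [], [], []
    for zyg, label in (("MZ", 1), ("DZ", -1)):
        pairs = cohort.twin_pairs(zyg)
        if not pairs:
            raise PreprocessError(f"cohort has no complete {zyg} pairs")
        for t1, t2 in pairs:
            rows.append(np.abs(data.loc[t1].to_numpy() - data.loc[t2].to_numpy()))
            labels.append(label)
            pair_ids.append(f"{t1}|{t2}")
    features = pd.DataFrame(np.vstack(rows), columns=list(data.columns))
    return PairFeatureSet(features=features, labels=np.array(labels),
                          pair_ids=pair_ids)


def oversample_balance(pairset: PairFeatureSet,
                       rng: np.random.Generator | int | None = 0) -> PairFeatureSet:
    """Oversample the minority class with replacement to match the majority.

    Majority rows are passed through untouched (exact multiset preserved);
    reproducible from the generator/seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = pairset.labels
    n_mz, n_dz = pairset.n_mz, pairset.n_dz
    if n_mz == 0 or n_dz == 0:
        raise PreprocessError("both classes must be present to balance")
    if n_mz == n_dz:
        return pairset
    minority = 1 if n_mz < n_dz else -1
    n_min, n_maj = min(n_mz, n_dz), max(n_mz, n_dz)
    min_idx = np.flatnonzero(labels == minority)
    extra = rng.choice(min_idx, size=n_maj - n_min, replace=True)
    keep = np.concatenate([np.arange(len(labels)), extra])
    return PairFeatureSet(
        features=pairset.features.iloc[keep].reset_index(drop=True),
        labels=labels[keep],
        pair_ids=[pairset.pair_ids[i] for i in keep],
    )
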