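"""Twin-cohort simulation with known variance components.

The classical twin design decomposes the variance of a standardized trait into
additive genetic (A), common-environment (C), non-additive/dominance genetic
(D) and unique-environment (E) fractions.  Within a twin pair the components
correlate at the textbook values: A at 1.0 (MZ) / 0.5 (DZ), D at 1.0 (MZ) /
0.25 (DZ), C at 1.0 for both zygosities, E at 0 for both.  Only three of the
four components are identifiable at once, so each measure is either an ACE or
an ADE model (``c2 * d2 == 0``).

Every downstream stage of the package is validated by parameter recovery on
cohorts produced here, so the simulator is first-class, fully seeded code:
identical ``(design, specs)`` and seed give a bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ", "NT")

#: within-pair correlation of each variance component, by zygosity
COMPONENT_TWIN_CORR = {
    "MZ": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0},
    "DZ": {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0},
}


class ValidationError(ValueError):
    """Raised when a variance spec or cohort design is internally inconsistent."""


@dataclass(frozen=True)
class VarianceSpec:
    """Ground-truth variance decomposition for one measure.

    Parameters
    ----------
    measure_id:
        Column label of the measure.
    a2, c2, d2, e2:
        Fractions of phenotypic variance from additive genes, common
        environment, dominance, and unique environment.  Must be
        non-negative, sum to 1, and satisfy ``c2 * d2 == 0`` (each measure is
        modeled as ACE or ADE, never ACDE).
    reliability:
        Target test-retest correlation in ``(0, 1]``.  1.0 means the measured
        phenotype equals the stable trait (no occasion noise).
    domain:
        ``"task"`` or ``"questionnaire"``; used by the domain permutation test.
    """

    measure_id: str
    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0
    reliability: float = 1.0
    domain: str = "task"

    def __post_init__(self) -> None:
        fracs = (self.a2, self.c2, self.d2, self.e2)
        if any(f < 0 for f in fracs):
            raise ValidationError(
                f"{self.measure_id}: variance fractions must be >= 0, got {fracs}"
            )
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ValidationError(
                f"{self.measure_id}: a2+c2+d2+e2 must equal 1, got {sum(fracs)!r}"
            )
        if self.c2 * self.d2 != 0.0:
            raise ValidationError(
                f"{self.measure_id}: c2*d2 must be 0 (ACE or ADE, not both); "
                f"got c2={self.c2}, d2={self.d2}"
            )
        if not (0.0 < self.reliability <= 1.0):
            raise ValidationError(
                f"{self.measure_id}: reliability must be in (0, 1], got {self.reliability}"
            )
        if self.domain not in ("task", "questionnaire"):
            raise ValidationError(
                f"{self.measure_id}: domain must be 'task' or 'questionnaire'"
            )

    def to_dict(self) -> dict:
        return {
            "measure_id": self.measure_id,
            "a2": self.a2,
            "c2": self.c2,
            "d2": self.d2,
            "e2": self.e2,
            "reliability": self.reliability,
            "domain": self.domain,
        }


def expected_twin_correlations(spec: VarianceSpec) -> tuple[float, float]:
    """Closed-form within-pair trait correlations implied by a variance spec.

    ``rMZ = a2 + d2 + c2`` and ``rDZ = 0.5*a2 + 0.25*d2 + c2``.  These are
    trait-level values; if ``reliability < 1`` the *measured* correlations are
    attenuated by the reliability.
    """
    r_mz = spec.a2 + spec.d2 + spec.c2
    r_dz = 0.5 * spec.a2 + 0.25 * spec.d2 + spec.c2
    return r_mz, r_dz


@dataclass(frozen=True)
class CohortDesign:
    """Size and correlation structure of a simulated cohort."""

    n_measures: int
    n_mz_pairs: int
    n_dz_pairs: int
    n_unrelated: int = 0
    n_retest: int = 0
    genetic_corr: np.ndarray | None = None
    env_corr: np.ndarray | None = None
    covariate_betas: np.ndarray | None = None
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_unrelated

    def __post_init__(self) -> None:
        if self.n_measures < 1:
            raise ValidationError("n_measures must be >= 1")
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_unrelated, self.n_retest) < 0:
            raise ValidationError("cohort counts must be >= 0")
        if self.n_retest > self.n_subjects:
            raise ValidationError("n_retest cannot exceed the number of subjects")
        for name in ("genetic_corr", "env_corr"):
            mat = getattr(self, name)
            if mat is not None:
                _validate_corr(np.asarray(mat, dtype=float), self.n_measures, name)
        if self.covariate_betas is not None:
            betas = np.asarray(self.covariate_betas, dtype=float)
            if betas.shape != (self.n_measures, 2):
                raise ValidationError(
                    f"covariate_betas must have shape (n_measures, 2), got {betas.shape}"
                )


def _validate_corr(mat: np.ndarray, m: int, name: str) -> None:
    if mat.shape != (m, m):
        raise ValidationError(f"{name} must be {m}x{m}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-8:
        raise ValidationError(f"{name} must be positive semidefinite")


@dataclass
class Cohort:
    """Simulated (or loaded) phenotype data with family structure.

    Attributes
    ----------
    phenotypes:
        subject x measure DataFrame indexed by subject_id; no missing values.
    subjects:
        DataFrame with columns subject_id, family_id, zygosity, age, sex.
    retest:
        Optional subset subject x measure DataFrame (second measurement
        occasion), indexed by subject_id.
    truth:
        For simulated cohorts, the VarianceSpec list, genetic correlation
        matrix and seed that generated the data; None when loaded from files
        without a truth record.
    """

    phenotypes: pd.DataFrame
    subjects: pd.DataFrame
    retest: pd.DataFrame | None = None
    truth: dict | None = None

    @property
    def measures(self) -> list[str]:
        return list(self.phenotypes.columns)

    def zygosity_of(self, subject_id: str) -> str:
        return self.subjects.set_index("subject_id").loc[subject_id, "zygosity"]

    def twin_pairs(self, zygosity: str) -> list[tuple[str, str]]:
        """Ordered (twin1, twin2) subject-id tuples for one zygosity."""
        sub = self.subjects[self.subjects.zygosity == zygosity]
        pairs = []
        for _, grp in sub.groupby("family_id", sort=True):
            ids = sorted(grp.subject_id)
            if len(ids) == 2:
                pairs.append((ids[0], ids[1]))
        return pairs

    def validate(self) -> None:
        if self.phenotypes.isna().any().any():
            raise ValidationError("phenotypes contain missing values")
        for zyg in ("MZ", "DZ"):
            sub = self.subjects[self.subjects.zygosity == zyg]
            sizes = sub.groupby("family_id").size()
            if not (sizes == 2).all():
                raise ValidationError(f"{zyg} families must have exactly two members")
        if self.retest is not None:
            missing = set(self.retest.index) - set(self.phenotypes.index)
            if missing:
                raise ValidationError(f"retest rows without phenotype rows: {missing}")


def _corr_factor(mat: np.ndarray | None, m: int) -> np.ndarray:
    """Matrix square root used to impose a cross-measure correlation."""
    if mat is None:
        return np.eye(m)
    mat = np.asarray(mat, dtype=float)
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        # PSD but singular: eigen factor with clipped negatives
        w, v = np.linalg.eigh(mat)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _paired_component(rng: np.random.Generator, n_pairs: int, m: int,
                      corr_factor: np.ndarray, within_r: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a component for twin1/twin2 with the given within-pair correlation.

    Cross-measure correlation (corr_factor @ corr_factor.T) holds marginally
    for each twin; within-pair correlation is ``within_r`` per measure.
    """
    shared = rng.standard_normal((n_pairs, m)) @ corr_factor.T
    if within_r >= 1.0:
        return shared, shared.copy()
    unique = rng.standard_normal((n_pairs, m)) @ corr_factor.T
    twin2 = within_r * shared + np.sqrt(1.0 - within_r**2) * unique
    return shared, twin2


def simulate_cohort(design: CohortDesign, specs: Sequence[VarianceSpec]) -> Cohort:
    """Simulate a twin cohort from ground-truth variance components.

    Each measured phenotype is
    ``sqrt(rel) * T + sqrt(1 - rel) * occasion_noise`` where the stable trait
    ``T = sqrt(a2)*A + sqrt(c2)*C + sqrt(d2)*D + sqrt(e2)*E`` and ``rel`` is
    the spec's target test-retest reliability.  Retest rows share ``T`` with
    an independent occasion-noise draw, so the expected test-retest Pearson
    correlation equals ``rel``.

    A-components follow ``design.genetic_corr`` across measures; C, D and E
    are independent across measures unless ``design.env_corr`` is given (then
    E follows it).  Age and sex are drawn independent of the phenotypes unless
    ``design.covariate_betas`` injects linear age/sex effects (used to test
    residualization).
    """
    if len(specs) != design.n_measures:
        raise ValidationError(
            f"got {len(specs)} specs for n_measures={design.n_measures}"
        )
    m = design.n_measures
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(design.seed).spawn(6)]
    rng_gen, rng_env, rng_noise, rng_retest, rng_cov, _ = rngs

    g_factor = _corr_factor(design.genetic_corr, m)
    e_factor = _corr_factor(design.env_corr, m)
    eye = np.eye(m)

    sqa = np.array([np.sqrt(s.a2) for s in specs])
    sqc = np.array([np.sqrt(s.c2) for s in specs])
    sqd = np.array([np.sqrt(s.d2) for s in specs])
    sqe = np.array([np.sqrt(s.e2) for s in specs])
    rel = np.array([s.reliability for s in specs])

    blocks: list[np.ndarray] = []
    meta: list[tuple[str, str]] = []  # (family_id, zygosity) per subject row

    fam = 0
    for zyg, n_pairs in (("MZ", design.n_mz_pairs), ("DZ", design.n_dz_pairs)):
        if n_pairs == 0:
            continue
        cr = COMPONENT_TWIN_CORR[zyg]
        a1, a2_ = _paired_component(rng_gen, n_pairs, m, g_factor, cr["A"])
        d1, d2_ = _paired_component(rng_gen, n_pairs, m, eye, cr["D"])
        c1, c2_ = _paired_component(rng_env, n_pairs, m, eye, cr["C"])
        e1 = rng_env.standard_normal((n_pairs, m)) @ e_factor.T
        e2_ = rng_env.standard_normal((n_pairs, m)) @ e_factor.T
        t1 = sqa * a1 + sqc * c1 + sqd * d1 + sqe * e1
        t2 = sqa * a2_ + sqc * c2_ + sqd * d2_ + sqe * e2_
        # interleave twin1/twin2 rows so pairs are adjacent
        both = np.empty((2 * n_pairs, m))
        both[0::2] = t1
        both[1::2] = t2
        blocks.append(both)
        for _ in range(n_pairs):
            fid = f"fam{fam:05d}"
            meta.extend([(fid, zyg), (fid, zyg)])
            fam += 1
    if design.n_unrelated:
        a = rng_gen.standard_normal((design.n_unrelated, m)) @ g_factor.T
        d = rng_gen.standard_normal((design.n_unrelated, m))
        c = rng_env.standard_normal((design.n_unrelated, m))
        e = rng_env.standard_normal((design.n_unrelated, m)) @ e_factor.T
        blocks.append(sqa * a + sqc * c + sqd * d + sqe * e)
        for _ in range(design.n_unrelated):
            meta.append((f"fam{fam:05d}", "NT"))
            fam += 1

    traits = np.vstack(blocks) if blocks else np.empty((0, m))
    n = traits.shape[0]

    age = rng_cov.integers(22, 36, size=n).astype(float)
    sex = rng_cov.integers(0, 2, size=n).astype(float)
    if design.covariate_betas is not None:
        betas = np.asarray(design.covariate_betas, dtype=float)
        age_std = (age - age.mean()) / age.std() if n > 1 else age * 0.0
        traits = traits + np.outer(age_std, betas[:, 0]) + np.outer(sex, betas[:, 1])

    sq_rel = np.sqrt(rel)
    sq_occ = np.sqrt(1.0 - rel)
    observed = sq_rel * traits + sq_occ * rng_noise.standard_normal((n, m))

    subject_ids = [f"s{i:05d}" for i in range(n)]
    measures = [s.measure_id for s in specs]
    phenotypes = pd.DataFrame(observed, index=subject_ids, columns=measures)
    phenotypes.index.name = "subject_id"
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "family_id": [f for f, _ in meta],
            "zygosity": [z for _, z in meta],
            "age": age,
            "sex": sex,
        }
    )

    retest = None
    if design.n_retest:
        idx = np.arange(design.n_retest)  # MZ subjects come first by layout
        retest_vals = (sq_rel * traits[idx]
                       + sq_occ * rng_retest.standard_normal((design.n_retest, m)))
        retest = pd.DataFrame(retest_vals,
                              index=[subject_ids[i] for i in idx],
                              columns=measures)
        retest.index.name = "subject_id"

    truth = {
        "specs": [s.to_dict() for s in specs],
        "genetic_corr": (None if design.genetic_corr is None
                         else np.asarray(design.genetic_corr).tolist()),
        "seed": design.seed,
    }
    cohort = Cohort(phenotypes=phenotypes, subjects=subjects, retest=retest,
                    truth=truth)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# correlation-structure recipes

def block_genetic_corr(sizes: Sequence[int], rho_within: float,
                       rho_between: float = 0.0) -> np.ndarray:
    """Block-structured genetic correlation matrix (blocks = latent factors)."""
    m = int(sum(sizes))
    mat = np.full((m, m), rho_between, dtype=float)
    start = 0
    for size in sizes:
        mat[start:start + size, start:start + size] = rho_within
        start += size
    np.fill_diagonal(mat, 1.0)
    _validate_corr(mat, m, "block_genetic_corr")
    return mat


def loading_corr(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a factor-loading recipe.

    ``R = L L' + diag(1 - rowSums(L^2))``; rows are measures, columns latent
    factors.  Row sums of squares must not exceed 1.
    """
    loadings = np.asarray(loadings, dtype=float)
    comm = (loadings**2).sum(axis=1)
    if (comm > 1.0 + 1e-12).any():
        raise ValidationError("factor loadings imply communalities > 1")
    mat = loadings @ loadings.T + np.diag(1.0 - comm)
    _validate_corr(mat, loadings.shape[0], "loading_corr")
    return mat


def block_loadings(sizes: Sequence[int], loading: float = 0.7) -> np.ndarray:
    """Simple-structure loading matrix: one factor per block of measures."""
    m, k = int(sum(sizes)), len(sizes)
    lam = np.zeros((m, k))
    start = 0
    for j, size in enumerate(sizes):
        lam[start:start + size, j] = loading
        start += size
    return lam


def simulate_factor_data(loadings: np.ndarray, n_subjects: int,
                         factor_corr: np.ndarray | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Draw subject x measure data from a common-factor model.

    ``X = F L' + E`` with latent factors ``F ~ N(0, Phi)`` and unique noise
    variances ``1 - communality``.  Used to exercise the factor-analysis
    stage with a known number of planted factors.
    """
    loadings = np.asarray(loadings, dtype=float)
    m, k = loadings.shape
    rng = np.random.default_rng(seed)
    if factor_corr is None:
        factors = rng.standard_normal((n_subjects, k))
    else:
        _validate_corr(np.asarray(factor_corr, dtype=float), k, "factor_corr")
        factors = rng.standard_normal((n_subjects, k)) @ _corr_factor(factor_corr, k).T
    uniq_sd = np.sqrt(np.clip(1.0 - (loadings**2).sum(axis=1), 0.0, None))
    data = factors @ loadings.T + rng.standard_normal((n_subjects, m)) * uniq_sd
    return pd.DataFrame(data, columns=[f"m{i:02d}" for i in range(m)])


# ---------------------------------------------------------------------------
# on-disk format: two CSVs + truth JSON

def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = cohort.subjects.set_index("subject_id").join(cohort.phenotypes)
    table.to_csv(directory / "phenotypes.csv")
    if cohort.retest is not None:
        cohort.retest.to_csv(directory / "retest.csv")
    if cohort.truth is not None:
        (directory / "truth.json").write_text(json.dumps(cohort.truth, indent=1))


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    table = pd.read_csv(directory / "phenotypes.csv", index_col="subject_id")
    subject_cols = ["family_id", "zygosity", "age", "sex"]
    subjects = table[subject_cols].reset_index()
    phenotypes = table.drop(columns=subject_cols)
    retest_path = directory / "retest.csv"
    retest = (pd.read_csv(retest_path, index_col="subject_id")
              if retest_path.exists() else None)
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    cohort = Cohort(phenotypes=phenotypes, subjects=subjects, retest=retest,
                    truth=truth)
    cohort.validate()
    return cohort
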