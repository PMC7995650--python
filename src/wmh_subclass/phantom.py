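"""Synthetic 3D phantoms and cohorts with known ground truth.

A phantom subject is a small brain-like geometry: an ellipsoidal brain,
two ellipsoidal lateral ventricles, and an extended ventricle mask
obtained by dilating the ventricles.  Lesions are random-walk-grown
blobs — periventricular ones seeded inside the extended ventricle
margin, deep ones grown with zero overlap — each optionally carrying a
low-PVE hypointense core placed in its morphological interior and
surrounded by a high-PVE rim.  DTI maps assign tissue-specific means
(normal-appearing white matter, rim, core) with the core shifted toward
lower FA and higher MD/AD/RD, plus Gaussian noise.

Cohort generation supports two regimes: *image-based* (each subject is a
rendered phantom whose measured volumes feed the cognitive scores) for
end-to-end pipeline checks at small n, and *parametric* (sub-class
volumes drawn from a log-normal one-factor model matched to realistic
cohort moments) for the large Monte-Carlo studies of the regression
machinery, where rendering hundreds of thousands of images would add
nothing to what is being tested.

All randomness flows through a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .intensity_classify import split_by_pve
from .location_classify import (
    SUBCLASS_CODES,
    classify_location,
    combine_subclasses,
    label_clusters,
)
from .volumes_io import BinaryMask, CohortTable, SubjectBundle, VoxelGrid
from .volumetrics_dti import compute_volumes, summarize_dti

__all__ = [
    "PhantomSpec",
    "LesionTruth",
    "GroundTruth",
    "CohortTruth",
    "PlacementError",
    "generate_subject",
    "generate_cohort",
    "cohort_dti_means",
    "beta_for_f2",
]

DTI_METRICS = ("FA", "MD", "AD", "RD")

#: tissue means per metric: (normal-appearing WM, rim, core).  Diffusivities
#: in mm^2/s x 10^-3.  The core is shifted toward lower FA and higher
#: MD/AD/RD relative to the rim, the contrast pattern of hypointense tissue.
DTI_TISSUE_MEANS: dict[str, tuple[float, float, float]] = {
    "FA": (0.45, 0.37, 0.26),
    "MD": (0.80, 0.92, 1.12),
    "AD": (1.25, 1.30, 1.42),
    "RD": (0.58, 0.73, 0.97),
}
DTI_NOISE_SD: dict[str, float] = {"FA": 0.04, "MD": 0.06, "AD": 0.08, "RD": 0.06}

# parametric cohort volume model (natural log of brain-adjusted volume):
# log v_c = LOGVOL_MEANS[c] + LOGVOL_LOADING*z + LOGVOL_RESID_SD*eps,
# one latent severity z per subject.  Means correspond to sub-class volumes
# of roughly 2.7 / 2.1 / 0.43 / 0.60 cm^3 in a 1.456 dm^3 brain.
LOGVOL_MEANS = {
    "log_peri_hypo": -6.30,
    "log_peri_nonhypo": -6.53,
    "log_deep_hypo": -8.12,
    "log_deep_nonhypo": -7.79,
}
LOGVOL_LOADING = 0.5
LOGVOL_RESID_SD = 0.65

#: mild demographic effects on every synthetic cognitive score
COVARIATE_BETAS = {
    "age": -0.03,
    "sex": 0.2,
    "education": 0.05,
    "systolic": -0.005,
    "diastolic": -0.005,
}

_SCORE_BASELINES = {
    "moca": 27.0,
    "tmt_a": 31.0,
    "tmt_b": 67.0,
    "tmt_b_minus_a": 36.0,
    "digit_span_forward": 11.0,
    "digit_span_backwards": 9.7,
    "digit_span_sequence": 10.0,
    "digit_symbol": 31.0,
    "digit_coding": 63.0,
    "bnt_60": 57.0,
    "letter_fluency": 15.8,
    "category_fluency": 22.4,
}


class PlacementError(RuntimeError):
    """Lesions could not be placed within the geometric constraints."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Lesion sizes follow a log-normal law (median in voxels, dispersion on
    the log scale).  ``core_probability`` is the chance a lesion carries
    a hypointense core; the core occupies a uniform fraction of the
    lesion drawn from ``core_fraction_range`` and is placed at the
    lesion's interior (largest distance to the lesion boundary).
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semi_axes: tuple[float, float, float] = (16.0, 18.0, 16.0)
    ventricle_semi_axes: tuple[float, float, float] = (3.0, 8.0, 4.0)
    ventricle_offset: float = 6.0  # lateral shift of each ventricle (voxels)
    ventricle_margin: int = 2  # dilation iterations for the extended mask
    n_peri_lesions: int = 4
    n_deep_lesions: int = 4
    lesion_median_voxels: float = 15.0
    lesion_log_sigma: float = 0.8
    max_lesion_voxels: int = 150
    core_probability: float = 0.5
    core_fraction_range: tuple[float, float] = (0.2, 0.7)
    rim_pve: float = 0.8  # white-matter PVE on hyperintense (rim) voxels
    core_pve: float = 0.2  # white-matter PVE on hypointense (core) voxels
    background_pve: float = 0.85
    pve_noise_sd: float = 0.05
    dti_tissue_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DTI_TISSUE_MEANS)
    )
    dti_noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DTI_NOISE_SD))
    with_dti: bool = True
    seed: int = 0
    max_attempts: int = 200


@dataclass
class LesionTruth:
    lesion_id: int
    location: str  # "peri" | "deep"
    has_core: bool
    core_voxels: int
    rim_voxels: int

    @property
    def size_voxels(self) -> int:
        return self.core_voxels + self.rim_voxels


@dataclass
class GroundTruth:
    """Planted per-voxel codes and per-lesion records for one subject."""

    subclass_codes: np.ndarray | None
    lesions: list[LesionTruth]

    def counts(self) -> dict[str, int]:
        if self.subclass_codes is None:
            return {}
        return {
            name: int((self.subclass_codes == code).sum())
            for name, code in SUBCLASS_CODES.items()
        }


@dataclass
class CohortTruth:
    """What was planted into a synthetic cohort."""

    planted_beta: dict[str, float]
    covariate_beta: dict[str, float]
    noise_sd: float
    subjects: list[GroundTruth] = field(default_factory=list)


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d = sum(((grids[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    return d <= 1.0


_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)
_NEIGH6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=int
)


def _grow_lesion(
    seed_idx: tuple[int, int, int],
    target: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Random-walk growth from a seed voxel inside the allowed region.

    Repeatedly picks a random member voxel and a random 6-neighbour; the
    neighbour joins the lesion if allowed.  Gives up (returning what has
    grown) after a bounded number of stalled draws, so lesions in tight
    corners simply come out smaller.
    """
    shape = allowed.shape
    lesion = np.zeros(shape, dtype=bool)
    lesion[seed_idx] = True
    members = [seed_idx]
    stalls = 0
    while len(members) < target and stalls < 50 * target:
        base = members[rng.integers(len(members))]
        step = _NEIGH6[rng.integers(6)]
        cand = (base[0] + step[0], base[1] + step[1], base[2] + step[2])
        if not all(0 <= cand[k] < shape[k] for k in range(3)):
            stalls += 1
            continue
        if lesion[cand] or not allowed[cand]:
            stalls += 1
            continue
        lesion[cand] = True
        members.append(cand)
        stalls = 0
    return lesion


def _place_core(
    lesion: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Interior core voxels: deepest (distance-to-boundary) first."""
    size = int(lesion.sum())
    n_core = int(np.clip(round(fraction * size), 1, size))
    dist = ndimage.distance_transform_edt(lesion)
    idx = np.argwhere(lesion)
    depth = dist[tuple(idx.T)]
    # deepest first; random tie-break keeps cores from being axis-aligned
    order = np.lexsort((rng.random(len(idx)), -depth))
    core = np.zeros_like(lesion)
    core[tuple(idx[order[:n_core]].T)] = True
    return core


def generate_subject(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[SubjectBundle, GroundTruth]:
    """Render one phantom subject and its ground truth.

    Deterministic given ``spec.seed`` (or a caller-supplied generator).
    Lesions of the two location classes are kept mutually non-adjacent
    (26-neighbourhood separation), so the planted lesions are exactly the
    connected components of the WMH mask at any supported connectivity.

    Raises
    ------
    PlacementError
        If a lesion cannot be seeded after ``spec.max_attempts`` tries
        (grid too small or too crowded).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    center = (np.array(shape, dtype=float) - 1) / 2.0

    brain = _ellipsoid(shape, center, np.array(spec.brain_semi_axes))
    vent = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        c = center.copy()
        c[0] += sign * spec.ventricle_offset
        vent |= _ellipsoid(shape, c, np.array(spec.ventricle_semi_axes))
    vent &= brain
    vent_ext = ndimage.binary_dilation(vent, _STRUCT6, iterations=spec.ventricle_margin)
    vent_ext &= brain

    forbidden = np.zeros(shape, dtype=bool)  # placed lesions + 26-halo
    codes = np.zeros(shape, dtype=np.uint8)
    lesions: list[LesionTruth] = []
    plan = ["peri"] * spec.n_peri_lesions + ["deep"] * spec.n_deep_lesions

    for i, loc in enumerate(plan):
        if loc == "peri":
            allowed = brain & ~vent & ~forbidden
            seed_pool = allowed & vent_ext
        else:
            allowed = brain & ~vent & ~vent_ext & ~forbidden
            seed_pool = allowed
        lesion = None
        for _ in range(spec.max_attempts):
            seeds = np.argwhere(seed_pool)
            if len(seeds) == 0:
                break
            seed_idx = tuple(seeds[rng.integers(len(seeds))])
            target = int(
                np.clip(
                    round(
                        spec.lesion_median_voxels
                        * np.exp(spec.lesion_log_sigma * rng.standard_normal())
                    ),
                    1,
                    spec.max_lesion_voxels,
                )
            )
            grown = _grow_lesion(seed_idx, target, allowed, rng)
            if grown is not None and grown.any():
                lesion = grown
                break
        if lesion is None:
            raise PlacementError(
                f"could not place {loc} lesion {i + 1}/{len(plan)}; "
                "reduce lesion counts or enlarge the grid"
            )

        has_core = rng.random() < spec.core_probability
        core = np.zeros(shape, dtype=bool)
        if has_core:
            frac = rng.uniform(*spec.core_fraction_range)
            core = _place_core(lesion, frac, rng)
        rim = lesion & ~core
        peri = loc == "peri"
        codes[core] = SUBCLASS_CODES["peri_hypo" if peri else "deep_hypo"]
        codes[rim] = SUBCLASS_CODES["peri_nonhypo" if peri else "deep_nonhypo"]
        lesions.append(
            LesionTruth(
                lesion_id=i + 1,
                location=loc,
                has_core=bool(has_core and core.any()),
                core_voxels=int(core.sum()),
                rim_voxels=int(rim.sum()),
            )
        )
        forbidden |= ndimage.binary_dilation(lesion, _STRUCT26)

    wmh = codes > 0
    core_all = (codes == SUBCLASS_CODES["peri_hypo"]) | (codes == SUBCLASS_CODES["deep_hypo"])
    rim_all = wmh & ~core_all

    pve = np.zeros(shape, dtype=float)
    pve[brain] = spec.background_pve
    pve[vent] = 0.02
    pve[rim_all] = spec.rim_pve
    pve[core_all] = spec.core_pve
    if spec.pve_noise_sd > 0:
        pve = pve + spec.pve_noise_sd * rng.standard_normal(shape)
    pve = np.clip(pve, 0.0, 1.0)
    pve[~brain] = 0.0

    affine = np.diag(list(spec.voxel_dims) + [1.0])

    def grid(data: np.ndarray, dtype=float) -> VoxelGrid:
        return VoxelGrid(np.asarray(data, dtype=dtype), affine=affine.copy(), space_tag="phantom")

    dti: dict[str, VoxelGrid] | None = None
    if spec.with_dti:
        dti = {}
        for m in DTI_METRICS:
            bg, rim_mu, core_mu = spec.dti_tissue_means[m]
            vol = np.zeros(shape, dtype=float)
            vol[brain] = bg
            vol[vent] = 3.0 if m != "FA" else 0.08  # free-water-like CSF
            vol[rim_all] = rim_mu
            vol[core_all] = core_mu
            vol += spec.dti_noise_sd[m] * rng.standard_normal(shape)
            vol = np.clip(vol, 0.0, 1.0 if m == "FA" else None)
            vol[~brain] = 0.0
            dti[m] = grid(vol)

    bundle = SubjectBundle(
        wmh=BinaryMask(grid(wmh, dtype=np.uint8)),
        wm_pve=grid(pve),
        ventricle_ext=BinaryMask(grid(vent_ext, dtype=np.uint8)),
        brain=BinaryMask(grid(brain, dtype=np.uint8)),
        dti=dti,
    )
    return bundle, GroundTruth(subclass_codes=codes, lesions=lesions)


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": rng.uniform(60.0, 83.0, n).round(2),
            "sex": np.where(rng.random(n) < 0.81, "M", "F"),
            "education": rng.integers(13, 29, n).astype(float),
            "systolic": rng.normal(141.0, 17.5, n).round(1),
            "diastolic": rng.normal(77.0, 10.8, n).round(1),
        }
    )


def _parametric_log_volumes(n: int, rng: np.random.Generator) -> pd.DataFrame:
    z = rng.standard_normal(n)
    cols = {}
    for name, mu in LOGVOL_MEANS.items():
        cols[name] = mu + LOGVOL_LOADING * z + LOGVOL_RESID_SD * rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df["log_total"] = np.log(np.exp(df[list(LOGVOL_MEANS)]).sum(axis=1))
    return df


def _image_log_volumes(
    n: int, template: PhantomSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    rows = []
    truths = []
    for _ in range(n):
        sub_spec = replace(
            template,
            n_peri_lesions=max(1, int(rng.poisson(template.n_peri_lesions))),
            n_deep_lesions=max(1, int(rng.poisson(template.n_deep_lesions))),
            with_dti=False,
        )
        bundle, truth = generate_subject(sub_spec, rng=rng)
        truths.append(truth)
        split = split_by_pve(bundle.wmh, bundle.wm_pve)
        clusters = label_clusters(bundle.wmh)
        peri = classify_location(clusters, bundle.ventricle_ext)
        smap = combine_subclasses(clusters, peri, split)
        report = compute_volumes(
            smap, brain_volume_dm3=bundle.brain_volume_dm3(), zero_policy="epsilon"
        )
        rows.append({f"log_{c}": report.log_adjusted[c] for c in report.log_adjusted})
    df = pd.DataFrame(rows)
    return df, truths


def generate_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    effect: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    image_based: bool = False,
    outcomes: tuple[str, ...] | None = None,
) -> tuple[CohortTable, CohortTruth]:
    """Synthetic cohort with planted covariate and volume effects.

    Cognitive scores are a linear combination of the demographic
    covariates and the log-adjusted volume predictors named in
    ``effect`` (keys must be volume predictor columns; values are slopes
    on the natural-log adjusted volume), plus Gaussian noise of sd
    ``noise_sd``.  With ``image_based=True`` the volume predictors are
    measured from rendered phantoms; otherwise they are drawn from the
    parametric log-normal factor model.
    """
    if n_subjects < 10:
        raise ValueError("cohort needs at least 10 subjects")
    rng = np.random.default_rng(seed)
    effect = dict(effect or {})
    valid = set(LOGVOL_MEANS) | {"log_total"}
    bad = set(effect) - valid
    if bad:
        raise ValueError(f"unknown effect predictors {sorted(bad)}; valid: {sorted(valid)}")

    df = _covariates(n_subjects, rng)
    truths: list[GroundTruth] = []
    if image_based:
        vols, truths = _image_log_volumes(n_subjects, spec or PhantomSpec(), rng)
    else:
        vols = _parametric_log_volumes(n_subjects, rng)
    df = pd.concat([df, vols], axis=1)

    sex01 = (df["sex"] == "M").astype(float)
    covar_part = (
        COVARIATE_BETAS["age"] * df["age"]
        + COVARIATE_BETAS["sex"] * sex01
        + COVARIATE_BETAS["education"] * df["education"]
        + COVARIATE_BETAS["systolic"] * df["systolic"]
        + COVARIATE_BETAS["diastolic"] * df["diastolic"]
    )
    planted_part = sum(
        (beta * df[name] for name, beta in effect.items()), start=pd.Series(0.0, index=df.index)
    )
    if outcomes is None:
        outcomes = tuple(_SCORE_BASELINES)
    for outcome in outcomes:
        base = _SCORE_BASELINES.get(outcome, 0.0)
        df[outcome] = (
            base + covar_part + planted_part + noise_sd * rng.standard_normal(n_subjects)
        )

    table = CohortTable(df=df, missing=df.isna())
    truth = CohortTruth(
        planted_beta=effect,
        covariate_beta=dict(COVARIATE_BETAS),
        noise_sd=noise_sd,
        subjects=truths,
    )
    return table, truth


def cohort_dti_means(
    n_subjects: int, spec: PhantomSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-subject DTI means inside hypo- and non-hypointense WMH masks.

    Renders ``n_subjects`` phantoms (cores guaranteed: the template's
    core probability is forced to 1) and returns one row per subject
    with columns ``{metric}_hypo`` / ``{metric}_nonhypo``.
    """
    template = replace(spec or PhantomSpec(), core_probability=1.0, with_dti=True)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_subjects):
        bundle, _truth = generate_subject(template, rng=rng)
        split = split_by_pve(bundle.wmh, bundle.wm_pve)
        row: dict[str, float] = {}
        assert bundle.dti is not None
        for m in DTI_METRICS:
            row[f"{m}_hypo"] = summarize_dti(split.hypo, bundle.dti[m]).mean
            row[f"{m}_nonhypo"] = summarize_dti(split.non_hypo, bundle.dti[m]).mean
        rows.append(row)
    return pd.DataFrame(rows)


def beta_for_f2(f2: float, noise_sd: float, predictor: str = "log_peri_hypo") -> float:
    """Slope that plants a given partial effect size f^2 on one predictor.

    Under the parametric factor model the four sub-class log-volumes are
    jointly Gaussian; the slope needed for Cohen's f^2 on one of them,
    adjusting for the other three (the demographic covariates are
    independent of the volumes), is ``sqrt(f2) * noise_sd / sd_partial``
    where sd_partial is the conditional sd of that predictor given the
    other three.
    """
    if predictor not in LOGVOL_MEANS:
        raise ValueError(f"predictor must be one of {sorted(LOGVOL_MEANS)}")
    names = list(LOGVOL_MEANS)
    k = len(names)
    cov = np.full((k, k), LOGVOL_LOADING**2)
    np.fill_diagonal(cov, LOGVOL_LOADING**2 + LOGVOL_RESID_SD**2)
    i = names.index(predictor)
    rest = [j for j in range(k) if j != i]
    s11 = cov[i, i]
    s12 = cov[np.ix_([i], rest)]
    s22 = cov[np.ix_(rest, rest)]
    var_partial = s11 - (s12 @ np.linalg.solve(s22, s12.T))[0, 0]
    return float(np.sqrt(f2) * noise_sd / np.sqrt(var_partial))
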