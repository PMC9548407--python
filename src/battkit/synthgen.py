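"""Synthetic cohorts with the latent structure the battery analysis assumes.

Real multi-test data of this kind (chronic post-stroke aphasia cohorts with
item-level responses and lesion imaging) are ethics-restricted, so every
downstream stage is exercised on simulated cohorts whose generative
structure is known:

* Patients carry independent standard-normal latent abilities on a small
  number of orthogonal deficit factors (higher = better ability).
* Each test mixes the factors through a loading vector; the test score is a
  bounded affine transform of the noisy latent propensity, expressed in
  percent correct, and is decomposed into item-level correct/incorrect
  responses with graded item difficulty and discrimination.
* Controls score near ceiling with small spread and no latent deficit.
* Per-patient 3-D "abnormality" volumes place a smooth continuous lesion
  blob in factor-specific regions, scaled by (1 − normalised ability), so
  lesion-symptom mapping has a recoverable signal.

Every generator is a pure function of its configuration and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dimension import ScoreMatrix
from .reduction import ItemResponseMatrix

__all__ = [
    "LatentProfile",
    "TestSpec",
    "BatterySpec",
    "RegionAtlas",
    "simulate_cohort",
    "simulate_controls",
    "simulate_abnormality",
    "extensive_battery_preset",
    "shallow_battery_preset",
    "default_atlas",
    "DEFAULT_FACTORS",
]

DEFAULT_FACTORS = ["phonology", "semantics", "executive", "speech_quanta"]


@dataclass
class LatentProfile:
    """Per-patient latent abilities, one column per deficit factor."""

    values: np.ndarray  # n_patients × n_factors, higher = better ability
    factor_names: list[str]

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]


@dataclass
class TestSpec:
    """One test of a battery.

    ``loading_vector`` mixes the latent factors into the test's propensity;
    ``noise_sd`` is test-specific noise on that propensity (latent units);
    ``center``/``slope`` map propensity to percent correct;
    ``design_strata`` optionally partitions items into design cells (each
    stratum is factor-analysed separately during item reduction).
    """

    name: str
    loading_vector: np.ndarray
    n_items: int = 40
    noise_sd: float = 0.5
    center: float = 65.0
    slope: float = 18.0
    design_strata: list[list[int]] | None = None

    def __post_init__(self) -> None:
        self.loading_vector = np.asarray(self.loading_vector, dtype=float)
        if not np.all(np.isfinite(self.loading_vector)):
            raise ValueError(f"non-finite loading for test {self.name}")
        if self.n_items < 1:
            raise ValueError(f"non-positive n_items for test {self.name}")
        if self.noise_sd < 0:
            raise ValueError(f"negative noise_sd for test {self.name}")
        if self.design_strata is not None:
            flat = sorted(i for s in self.design_strata for i in s)
            if flat != list(range(self.n_items)):
                raise ValueError(
                    f"strata of {self.name} must partition items 0..{self.n_items - 1}")


@dataclass
class BatterySpec:
    """An ordered collection of :class:`TestSpec` with unique names."""

    tests: list[TestSpec]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            raise ValueError("test names must be unique")
        if not self.tests:
            raise ValueError("battery must contain at least one test")

    @property
    def test_names(self) -> list[str]:
        return [t.name for t in self.tests]

    def n_factors(self) -> int:
        return len(self.tests[0].loading_vector)


@dataclass
class RegionAtlas:
    """Disjoint boolean factor regions on a shared 3-D grid."""

    grid_shape: tuple[int, int, int]
    factor_regions: list[np.ndarray]
    background: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        occupied = np.zeros(self.grid_shape, dtype=bool)
        for i, reg in enumerate(self.factor_regions):
            reg = np.asarray(reg, dtype=bool)
            if reg.shape != tuple(self.grid_shape):
                raise ValueError("region shape does not match grid")
            if not reg.any():
                raise ValueError(f"factor region {i} is empty")
            if (occupied & reg).any():
                raise ValueError("factor regions must be pairwise disjoint")
            occupied |= reg
            self.factor_regions[i] = reg
        if self.background is None:
            self.background = ~occupied


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _item_parameters(test: TestSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Graded item difficulties and log-normal-ish discriminations.

    Difficulties are equally spaced quantiles of the propensity scale within
    each design stratum (so a factorial design has easy-to-hard items in
    every cell); discriminations vary so item reduction has a signal.
    """
    d = np.empty(test.n_items)
    strata = test.design_strata or [list(range(test.n_items))]
    for cell in strata:
        q = (np.arange(len(cell)) + 0.5) / len(cell)
        d[np.asarray(cell)] = norm.ppf(q) * 1.2
    a = np.exp(rng.normal(0.0, 0.45, size=test.n_items))
    return d, a


def simulate_cohort(spec: BatterySpec, n_patients: int, n_factors: int, seed: int,
                    ) -> tuple[LatentProfile, ScoreMatrix, dict[str, ItemResponseMatrix]]:
    """Simulate a patient cohort: latents, percent scores, item responses.

    For patient p and test t the latent propensity is
    ``eta = loading_t · latent_p + N(0, noise_sd_t)``; the percent score is
    the bounded affine transform ``clip(center + slope * eta, 0, 100)``,
    and ``round(score * n_items / 100)`` items are
    marked correct — those with the highest noisy two-parameter (difficulty,
    discrimination) probit propensities — so the item sum reproduces the
    score exactly and easier/more discriminating items are passed first.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    for t in spec.tests:
        if len(t.loading_vector) != n_factors:
            raise ValueError(f"test {t.name} loading length != n_factors")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_patients, n_factors))
    profile = LatentProfile(latent, DEFAULT_FACTORS[:n_factors] if n_factors <= 4
                            else [f"F{i + 1}" for i in range(n_factors)])

    patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    scores = np.empty((n_patients, len(spec.tests)))
    items: dict[str, ItemResponseMatrix] = {}

    for j, test in enumerate(spec.tests):
        eta = latent @ test.loading_vector
        if test.noise_sd > 0:
            eta = eta + rng.normal(0.0, test.noise_sd, size=n_patients)
        pct = np.clip(test.center + test.slope * eta, 0.0, 100.0)
        scores[:, j] = pct
        n_correct = np.rint(pct * test.n_items / 100.0).astype(int)

        difficulty, discrim = _item_parameters(test, rng)
        # noisy probit propensity of each (patient, item) pair
        prop = discrim[None, :] * (eta[:, None] - difficulty[None, :])
        prop = prop + rng.normal(0.0, 1.0, size=prop.shape)
        resp = np.zeros((n_patients, test.n_items), dtype=float)
        order = np.argsort(-prop, axis=1, kind="stable")
        for p in range(n_patients):
            resp[p, order[p, : n_correct[p]]] = 1.0

        items[test.name] = ItemResponseMatrix(
            values=resp,
            patient_ids=patient_ids,
            item_ids=[f"{test.name}_i{i + 1:03d}" for i in range(test.n_items)],
            test_name=test.name,
            strata=test.design_strata,
        )

    score_matrix = ScoreMatrix(scores, patient_ids, spec.test_names)
    return profile, score_matrix, items


def simulate_controls(spec: BatterySpec, n_controls: int, seed: int,
                      ceiling_mean: float = 97.0, ceiling_sd: float = 1.5,
                      ) -> ScoreMatrix:
    """Neurologically healthy controls: near-ceiling scores, no deficit factor."""
    if n_controls < 2:
        raise ValueError("need at least 2 controls to later compute an SD")
    if ceiling_sd < 0:
        raise ValueError("negative ceiling_sd")
    rng = np.random.default_rng(seed)
    raw = rng.normal(ceiling_mean, ceiling_sd, size=(n_controls, len(spec.tests)))
    vals = np.clip(raw, 0.0, 100.0)
    ids = [f"C{i + 1:03d}" for i in range(n_controls)]
    return ScoreMatrix(vals, ids, spec.test_names)


# ---------------------------------------------------------------------------
# abnormality volumes
# ---------------------------------------------------------------------------


def simulate_abnormality(latent: LatentProfile, atlas: RegionAtlas, seed: int,
                         baseline_noise: float = 0.05, profile_sd: float = 2.5,
                         ) -> tuple[list[np.ndarray], np.ndarray]:
    """Continuous [0, 1] abnormality volumes tied to the latent factors.

    Each factor region receives a smooth radial blob centred on the region's
    centre of mass, with peak amplitude ``1 − Φ(latent_r)`` (Φ the standard
    normal CDF), i.e. worse ability on factor r ⇒ more abnormal tissue in
    region r.  Background voxels carry uniform U(0, baseline_noise) scanner
    noise.  ``lesion_volume`` is the per-patient sum of abnormality over the
    whole grid (voxel units).
    """
    shape = tuple(atlas.grid_shape)
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    profiles = []
    for reg in atlas.factor_regions:
        com = np.array(np.nonzero(reg)).mean(axis=1)
        dist2 = np.sum((coords - com) ** 2, axis=-1)
        prof = np.exp(-dist2 / (2.0 * profile_sd**2))
        profiles.append(prof * reg)  # blob restricted to its region

    rng = np.random.default_rng(seed)
    volumes: list[np.ndarray] = []
    severity = 1.0 - norm.cdf(latent.values)  # n_patients × n_factors, in (0,1)
    for p in range(latent.n_patients):
        vol = rng.uniform(0.0, baseline_noise, size=shape)
        for r, prof in enumerate(profiles):
            vol = np.maximum(vol, severity[p, r] * prof)
        volumes.append(np.clip(vol, 0.0, 1.0))
    lesion_volumes = np.array([float(v.sum()) for v in volumes])
    return volumes, lesion_volumes


def default_atlas(grid_shape: tuple[int, int, int] = (14, 14, 14),
                  n_factors: int = 4, region_radius: float = 2.2) -> RegionAtlas:
    """Four well-separated spherical factor regions on a small grid."""
    shape = tuple(grid_shape)
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    lo = np.array(shape) * 0.28
    hi = np.array(shape) * 0.72
    centres = [
        (lo[0], lo[1], lo[2]), (hi[0], hi[1], lo[2]),
        (lo[0], hi[1], hi[2]), (hi[0], lo[1], hi[2]),
        (hi[0], hi[1], hi[2]), (lo[0], lo[1], hi[2]),
    ][:n_factors]
    regions = []
    for c in centres:
        dist2 = np.sum((coords - np.asarray(c)) ** 2, axis=-1)
        regions.append(dist2 <= region_radius**2)
    return RegionAtlas(shape, regions)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def extensive_battery_preset() -> BatterySpec:
    """Default deep battery: 22 tests driven by 4 orthogonal factors.

    Two designated high-loading (0.85) proxy tests per factor plus mixed-
    and moderate-loading tests, mirroring the simple-structure outcome seen
    in deep aphasia batteries (phonology, semantics, executive, speech
    quanta) without copying any copyrighted test content.  Noise is set so
    leave-one-out generalisability of the 4-component solution lands in the
    high-0.8s, the band reported for comparable real batteries.
    """
    F = np.eye(4)
    t = []

    def mk(name, load, n_items=40, noise=0.35, strata=None):
        t.append(TestSpec(name, load, n_items=n_items, noise_sd=noise,
                          design_strata=strata))

    # designated proxies: two per factor, high target loading, near-zero off,
    # low test-specific noise (deep tests measure their factor reliably)
    mk("nonword_repetition", 0.85 * F[0], noise=0.3)
    mk("word_repetition", 0.85 * F[0], noise=0.3)
    mk("synonym_judgement", 0.85 * F[1], n_items=96, noise=0.3,
       strata=[list(range(0, 48)), list(range(48, 96))])
    mk("picture_naming_long", 0.85 * F[1], n_items=60, noise=0.3)
    mk("matrix_reasoning", 0.85 * F[2], noise=0.3)
    mk("spatial_anticipation", 0.85 * F[2], noise=0.3)
    mk("words_per_minute", 0.85 * F[3], noise=0.3)
    mk("utterance_length", 0.85 * F[3], noise=0.3)

    # moderate single-factor tests (noisier, shallower measures)
    mk("minimal_pairs_words", 0.6 * F[0], noise=0.55)
    mk("minimal_pairs_nonwords", 0.6 * F[0], noise=0.55)
    mk("spoken_word_picture_match", 0.6 * F[1], noise=0.55)
    mk("written_word_picture_match", 0.6 * F[1], noise=0.55)
    mk("semantic_association", 0.6 * F[1], n_items=64, noise=0.55)
    mk("rule_shift", 0.6 * F[2], noise=0.55)
    mk("token_count", 0.6 * F[3], noise=0.55)

    # mixed-loading tests (tasks are never factor-pure)
    mk("delayed_word_repetition", 0.65 * F[0] + 0.35 * F[1])
    mk("delayed_nonword_repetition", 0.7 * F[0] + 0.25 * F[2])
    mk("picture_naming_short", 0.55 * F[1] + 0.45 * F[0])
    mk("sentence_comprehension", 0.5 * F[1] + 0.45 * F[2])
    mk("digit_span_forward", 0.6 * F[0] + 0.35 * F[2])
    mk("digit_span_backward", 0.5 * F[2] + 0.45 * F[0])
    mk("type_token_ratio", 0.6 * F[3] + 0.3 * F[1])

    return BatterySpec(t)


def shallow_battery_preset() -> BatterySpec:
    """Shallow screening battery: many short, ceiling-compressed subtests.

    Few items per test and a high, flat percent mapping compress the dynamic
    range near ceiling, reproducing the reduced sensitivity of clinical
    screeners to mild deficits.
    """
    F = np.eye(4)
    combos = [
        ("s_word_rep", 0.8 * F[0]), ("s_nonword_rep", 0.75 * F[0]),
        ("s_naming", 0.6 * F[1] + 0.3 * F[0]), ("s_semantic_memory", 0.7 * F[1]),
        ("s_spoken_words", 0.6 * F[1] + 0.3 * F[0]), ("s_written_words", 0.65 * F[1]),
        ("s_fluency", 0.6 * F[3] + 0.3 * F[2]), ("s_speed", 0.7 * F[3]),
        ("s_arithmetic", 0.7 * F[2]), ("s_recognition_memory", 0.6 * F[2] + 0.2 * F[1]),
        ("s_line_bisection", 0.5 * F[2]), ("s_digit_span", 0.6 * F[0] + 0.3 * F[2]),
    ]
    tests = [TestSpec(name, load, n_items=8, noise_sd=0.6, center=88.0, slope=9.0)
             for name, load in combos]
    return BatterySpec(tests)
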