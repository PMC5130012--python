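"""Seeded synthetic plates, screens, dose-response tables and images.

The generators emulate the statistical structure of a larval pigmentation
screen so that every downstream stage is testable without real data:

* absorbance plates with casper background wells, wild-type wells and
  vehicle-treated V12RAS control wells, calibrated so the background-
  subtracted transgenic/wild-type ratio is 1.43;
* a full screen preset (640 compounds, spiked suppressors, one-off primary
  flukes, toxic wells) whose hit cascade resolves to 37 primary hits,
  25 retest survivors and 11 triaged hits by construction;
* median-effect dose-response and constant-ratio combination tables with a
  prescribed combination index;
* spot-rendered larval images and disc-rendered spheroid images with exact
  pixel-level ground truth.

Compound effects act multiplicatively on the signal excess over the casper
background: signal = casper + effect * (v12ras - casper), so an effect of
0.5 halves the excess melanin.  Control wells of screen plates are rendered
at their exact means; bounded noise is placed on treatment wells only, which
keeps the normalization scale exact and makes the cascade counts
reproducible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, NumericalError
from .screen_io import WELL_COLUMNS, PlateLayout, sort_wells

__all__ = [
    "SyntheticScreenSpec",
    "MedianEffectParams",
    "ImageSpec",
    "ScreenSimulation",
    "generate_plate",
    "generate_screen",
    "generate_dose_response",
    "generate_combination",
    "generate_larva_image",
    "generate_spheroid_image",
    "generate_fold_experiments",
]

# Survival probabilities of the per-well binomial survival draw.
_P_SURVIVE_HEALTHY = 0.995
_P_SURVIVE_TOXIC = 0.4

# Triage profile construction (normalized units / dose multipliers).
_DOSE_MULTIPLIERS = (0.5, 1.0, 2.0, 4.0)
_DOSE_EFFECTS_GRADED = (0.95, 0.80, 0.65, 0.50)
_SINGLE_AGENT_EFFECT = 0.80
_SINGLE_AGENT_EFFECT_NO_COOP = 0.50
_WT_SUPPRESS_EFFECT = 0.2


@dataclass
class SyntheticScreenSpec:
    """Study-scale parameters of the synthetic screen.

    Defaults are the screen preset: a 640-compound library read once per
    compound in combination with a backbone inhibitor, 25 genuine
    suppressors at normalized signal 0.55, 12 null compounds whose single
    primary well is a one-off fluke at the same level, and 11 suppressors
    additionally given dose-dependent, cooperative, wild-type-sparing
    follow-up profiles.  Raw control means are calibrated so that
    (v12ras - casper)/(wt - casper) = 1.43.
    """

    n_compounds: int = 640
    n_true_suppressors: int = 25
    n_primary_flukes: int = 12
    n_triage_pass: int = 11
    true_effect: float = 0.55
    noise_model: str = "uniform_bounded"
    noise_scale: float = 0.04
    casper_mean: float = 0.05
    wt_mean: float = 0.35
    v12ras_mean: float = 0.479
    wells_per_compound_primary: int = 1
    wells_per_compound_retest: int = 5
    toxic_fraction: float = 0.05
    embryos_per_well: int = 10
    library_dose_um: float = 1.0
    arm: str = "compound_plus_mek"
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_suppressors + self.n_primary_flukes > self.n_compounds:
            raise ConfigurationError(
                "n_true_suppressors + n_primary_flukes exceeds n_compounds"
            )
        if self.n_triage_pass > self.n_true_suppressors:
            raise ConfigurationError("n_triage_pass exceeds n_true_suppressors")
        if not self.casper_mean < self.wt_mean < self.v12ras_mean:
            raise ConfigurationError(
                "means must satisfy casper_mean < wt_mean < v12ras_mean"
            )
        if self.noise_model not in {"gaussian", "uniform_bounded"}:
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if not 0 <= self.toxic_fraction <= 1:
            raise ConfigurationError("toxic_fraction must lie in [0, 1]")
        n_toxic = round(self.toxic_fraction * self.n_compounds)
        spoken = self.n_true_suppressors + self.n_primary_flukes + n_toxic
        if spoken > self.n_compounds:
            raise ConfigurationError(
                "not enough null compounds to host the toxic fraction"
            )
        if self.noise_scale < 0 or self.embryos_per_well <= 0:
            raise ConfigurationError("noise_scale and embryos_per_well invalid")

    @property
    def delta(self) -> float:
        """Raw-absorbance span of the normalized scale."""
        return self.v12ras_mean - self.casper_mean


@dataclass(frozen=True)
class MedianEffectParams:
    """True (Dm, m) of a generating median-effect model."""

    dm: float
    m: float

    def __post_init__(self) -> None:
        if self.dm <= 0 or self.m <= 0:
            raise ConfigurationError("MedianEffectParams requires Dm > 0, m > 0")

    def fa(self, dose):
        r = (np.asarray(dose, float) / self.dm) ** self.m
        return r / (1.0 + r)

    def dx(self, fa):
        fa = np.asarray(fa, float)
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class ImageSpec:
    """Geometry and rendering parameters of a synthetic larval image.

    ``roi`` is (left, top, width, height) in pixels, top-left origin,
    half-open.  Spots are dark filled discs on a lighter noisy background;
    centers are spaced at least 2*max_radius + 2 px apart so the discs stay
    disjoint under 8-connectivity and the component count equals n_spots.
    """

    width: int = 1100
    height: int = 600
    roi: tuple[int, int, int, int] = (50, 50, 1000, 500)
    n_spots: int = 40
    spot_radius_range: tuple[int, int] = (3, 6)
    spot_intensity: int = 60
    background_intensity: int = 200
    noise_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        left, top, w, h = self.roi
        if left < 0 or top < 0 or left + w > self.width or top + h > self.height:
            raise ConfigurationError("roi extends outside the image")
        if not 0 < self.spot_radius_range[0] <= self.spot_radius_range[1]:
            raise ConfigurationError("invalid spot_radius_range")
        if self.spot_intensity >= self.background_intensity:
            raise ConfigurationError(
                "spot_intensity must be darker than background_intensity"
            )
        if self.n_spots < 0 or self.noise_sd < 0:
            raise ConfigurationError("n_spots and noise_sd must be non-negative")


@dataclass
class ScreenSimulation:
    """All tables of one simulated screen plus per-compound ground truth.

    ``truth`` columns: compound_id, category (null|suppressor|fluke),
    toxic (bool), triage_profile ('' | pass | flat_dose | no_coop |
    wt_suppress).
    """

    spec: SyntheticScreenSpec
    truth: pd.DataFrame
    primary_wells: pd.DataFrame
    rescreen_wells: pd.DataFrame
    retest_wells: pd.DataFrame
    dose_wells: pd.DataFrame
    wt_wells: pd.DataFrame
    combo_wells: pd.DataFrame


def _noise(rng: np.random.Generator, spec: SyntheticScreenSpec) -> float:
    if spec.noise_scale == 0:
        return 0.0
    if spec.noise_model == "uniform_bounded":
        return float(rng.uniform(-spec.noise_scale, spec.noise_scale))
    return float(rng.normal(0.0, spec.noise_scale))


def _survival(rng: np.random.Generator, spec: SyntheticScreenSpec, toxic: bool) -> int:
    n = spec.embryos_per_well
    if toxic:
        drawn = int(rng.binomial(n, _P_SURVIVE_TOXIC))
        # the postcondition that a toxic well fails the 80% threshold is
        # enforced on the drawn count
        return min(drawn, int(np.ceil(0.8 * n)) - 1)
    return int(rng.binomial(n, _P_SURVIVE_HEALTHY))


def _role_mean(role: str, spec: SyntheticScreenSpec, effect: float) -> float:
    if role == "casper":
        return spec.casper_mean
    if role == "v12ras_dmso":
        return spec.v12ras_mean
    if role == "wt":
        # effect acts on the wild-type excess over background
        return spec.casper_mean + effect * (spec.wt_mean - spec.casper_mean)
    # compound wells: effect acts on the transgenic excess over background
    return spec.casper_mean + effect * spec.delta


def generate_plate(
    spec: SyntheticScreenSpec,
    layout: PlateLayout,
    effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Render one plate of well records from a declared layout.

    ``effects`` maps compound_id to its multiplicative effect on the excess
    signal (default 1.0, i.e. inactive).  Every well gets its role mean plus
    noise; deterministic given ``spec.seed``.
    """
    spec.validate()
    layout.validate(require_controls=True)
    effects = effects or {}
    rng = np.random.default_rng(spec.seed)
    rows = []
    for addr, role, compound_id, dose in layout.wells:
        effect = effects.get(compound_id, 1.0) if compound_id else 1.0
        raw = _role_mean(role, spec, effect) + _noise(rng, spec) * spec.delta
        rows.append(
            {
                "plate_id": layout.plate_id,
                "well": addr,
                "role": role,
                "compound_id": compound_id or "",
                "dose_um": dose,
                "raw_absorbance": max(raw, 0.0),
                "wavelength_nm": 340,
                "embryos_in": spec.embryos_per_well,
                "embryos_alive": _survival(rng, spec, toxic=False),
            }
        )
    return sort_wells(pd.DataFrame(rows, columns=WELL_COLUMNS))


@dataclass
class _Entry:
    role: str
    compound_id: str
    dose_um: float
    effect: float
    toxic: bool = False


def _addresses(n: int) -> list[str]:
    rows = "ABCDEFGH"
    out = []
    r = 0
    while len(out) < n:
        for c in range(1, 7):
            out.append(f"{rows[r]}{c}")
            if len(out) == n:
                break
        r += 1
    return out


def _build_plates(
    entries: list[_Entry],
    prefix: str,
    spec: SyntheticScreenSpec,
    rng: np.random.Generator,
    content_per_plate: int = 20,
    n_casper: int = 2,
    n_dmso: int = 2,
) -> pd.DataFrame:
    """Lay entries onto 24-well plates, each carrying exact-mean controls."""
    if not entries:
        return pd.DataFrame(columns=WELL_COLUMNS)
    rows = []
    plate_no = 0
    for start in range(0, len(entries), content_per_plate):
        chunk = entries[start : start + content_per_plate]
        plate_no += 1
        plate_id = f"{prefix}{plate_no:03d}"
        addrs = _addresses(n_casper + n_dmso + len(chunk))
        plate_entries = (
            [_Entry("casper", "", np.nan, 1.0)] * n_casper
            + [_Entry("v12ras_dmso", "", np.nan, 1.0)] * n_dmso
            + chunk
        )
        for addr, e in zip(addrs, plate_entries):
            if e.role in ("casper", "v12ras_dmso"):
                raw = _role_mean(e.role, spec, 1.0)  # exact control means
            else:
                raw = _role_mean(e.role, spec, e.effect) + _noise(rng, spec) * spec.delta
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": addr,
                    "role": e.role,
                    "compound_id": e.compound_id,
                    "dose_um": e.dose_um,
                    "raw_absorbance": max(raw, 0.0),
                    "wavelength_nm": 340,
                    "embryos_in": spec.embryos_per_well,
                    "embryos_alive": _survival(rng, spec, e.toxic),
                }
            )
    return sort_wells(pd.DataFrame(rows, columns=WELL_COLUMNS))


def generate_screen(spec: SyntheticScreenSpec | None = None) -> ScreenSimulation:
    """Generate a full screen: primary, rescreen, retest and triage tables.

    Spiking plan (all assignments drawn from ``spec.seed``):

    * ``n_true_suppressors`` compounds read at ``true_effect`` everywhere;
    * ``n_primary_flukes`` null compounds read at ``true_effect`` in their
      primary well only and revert to null on retest;
    * a ``toxic_fraction`` of null compounds fails embryo survival in the
      primary pass and is rescreened clean at half dose;
    * of the suppressors, ``n_triage_pass`` get follow-up profiles passing
      all three triage predicates; the rest cycle through single-predicate
      failure modes (flat dose series, no cooperation, wild-type
      suppression).
    """
    spec = spec or SyntheticScreenSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    ids = np.array([f"C{i:04d}" for i in range(1, n + 1)])
    perm = rng.permutation(n)
    suppressors = list(ids[perm[: spec.n_true_suppressors]])
    flukes = list(
        ids[perm[spec.n_true_suppressors : spec.n_true_suppressors + spec.n_primary_flukes]]
    )
    n_toxic = round(spec.toxic_fraction * n)
    toxic = set(
        ids[
            perm[
                spec.n_true_suppressors
                + spec.n_primary_flukes : spec.n_true_suppressors
                + spec.n_primary_flukes
                + n_toxic
            ]
        ]
    )
    pass_set = set(suppressors[: spec.n_triage_pass])
    fail_modes = ("flat_dose", "no_coop", "wt_suppress")
    profile = {}
    for i, cid in enumerate(suppressors):
        profile[cid] = "pass" if cid in pass_set else fail_modes[i % 3]

    sup_set, fluke_set = set(suppressors), set(flukes)
    truth = pd.DataFrame(
        {
            "compound_id": ids,
            "category": [
                "suppressor" if c in sup_set else "fluke" if c in fluke_set else "null"
                for c in ids
            ],
            "toxic": [c in toxic for c in ids],
            "triage_profile": [profile.get(c, "") for c in ids],
        }
    )

    # --- primary pass: one well per compound, in library order -------------
    primary_entries = []
    for cid in ids:
        effect = spec.true_effect if (cid in sup_set or cid in fluke_set) else 1.0
        for _ in range(spec.wells_per_compound_primary):
            primary_entries.append(
                _Entry(spec.arm, cid, spec.library_dose_um, effect, toxic=cid in toxic)
            )
    primary = _build_plates(primary_entries, "P", spec, rng)

    # --- rescreen of toxic compounds at half dose --------------------------
    rescreen_entries = [
        _Entry(spec.arm, cid, spec.library_dose_um / 2.0, 1.0)
        for cid in sorted(toxic)
    ]
    rescreen = _build_plates(rescreen_entries, "R", spec, rng)

    # --- retest: replicate wells for suppressors and flukes ----------------
    retest_entries = []
    for cid in sorted(sup_set | fluke_set):
        effect = spec.true_effect if cid in sup_set else 1.0
        for _ in range(spec.wells_per_compound_retest):
            retest_entries.append(_Entry(spec.arm, cid, spec.library_dose_um, effect))
    retest = _build_plates(retest_entries, "T", spec, rng)

    # --- triage tables for all suppressors ---------------------------------
    dose_entries, wt_entries, combo_entries = [], [], []
    wt_entries.extend(_Entry("wt", "", np.nan, 1.0) for _ in range(3))  # baseline
    for cid in sorted(sup_set):
        mode = profile[cid]
        effects = (
            [spec.true_effect] * 4 if mode == "flat_dose" else list(_DOSE_EFFECTS_GRADED)
        )
        for mult, eff in zip(_DOSE_MULTIPLIERS, effects):
            dose_entries.append(
                _Entry(spec.arm, cid, spec.library_dose_um * mult, eff)
            )
        wt_eff = _WT_SUPPRESS_EFFECT if mode == "wt_suppress" else 1.0
        wt_entries.extend(
            _Entry("wt", cid, spec.library_dose_um, wt_eff) for _ in range(3)
        )
        single_eff = (
            _SINGLE_AGENT_EFFECT_NO_COOP if mode == "no_coop" else _SINGLE_AGENT_EFFECT
        )
        combo_entries.extend(
            _Entry("compound", cid, spec.library_dose_um, single_eff) for _ in range(3)
        )
        combo_entries.extend(
            _Entry(spec.arm, cid, spec.library_dose_um, spec.true_effect)
            for _ in range(3)
        )
    dose_wells = _build_plates(dose_entries, "D", spec, rng)
    wt_wells = _build_plates(wt_entries, "W", spec, rng)
    combo_wells = _build_plates(combo_entries, "S", spec, rng)

    return ScreenSimulation(
        spec=spec,
        truth=truth,
        primary_wells=primary,
        rescreen_wells=rescreen,
        retest_wells=retest,
        dose_wells=dose_wells,
        wt_wells=wt_wells,
        combo_wells=combo_wells,
    )


def generate_dose_response(
    params: MedianEffectParams,
    doses,
    fa_noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fraction-affected table from a median-effect model, optionally noisy."""
    doses = np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    fa = params.fa(doses)
    if fa_noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa + rng.normal(0.0, fa_noise_sd, size=fa.shape)
    fa = np.clip(fa, 1e-9, 1.0 - 1e-9)
    return pd.DataFrame({"dose_um": doses, "fraction_affected": fa})


def generate_combination(
    params1: MedianEffectParams,
    params2: MedianEffectParams,
    ratio: tuple[float, float],
    target_ci: float,
    total_doses,
) -> pd.DataFrame:
    """Constant-ratio combination table realizing a prescribed CI.

    Each total dose is split per ``ratio`` into (d1, d2); the observed
    fraction affected is the unique solution of

        d1 / Dx1(fa) + d2 / Dx2(fa) = target_ci,

    found by root bracketing on fa in (0, 1).  ``target_ci = 1`` yields an
    exactly Loewe-additive response surface.
    """
    if target_ci <= 0:
        raise ValueError("target_ci must be positive")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio components must be positive")
    rows = []
    lo, hi = 1e-12, 1.0 - 1e-12
    for total in np.asarray(total_doses, float):
        if total <= 0:
            raise ValueError("total doses must be positive")
        d1 = total * a / (a + b)
        d2 = total * b / (a + b)

        def g(fa, d1=d1, d2=d2):
            return d1 / params1.dx(fa) + d2 / params2.dx(fa) - target_ci

        glo, ghi = g(lo), g(hi)
        if not (np.isfinite(glo) and np.isfinite(ghi)) or glo * ghi > 0:
            raise NumericalError(
                f"generate_combination: no sign change on (0,1) bracket for "
                f"total dose {total:g} (g({lo:g})={glo:g}, g({hi:g})={ghi:g})"
            )
        fa = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
        rows.append({"d1": d1, "d2": d2, "fraction_affected": float(fa)})
    return pd.DataFrame(rows, columns=["d1", "d2", "fraction_affected"])


def _place_spots(
    spec: ImageSpec, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    left, top, w, h = spec.roi
    r_min, r_max = spec.spot_radius_range
    min_dist2 = (2 * r_max + 2) ** 2
    centers: list[tuple[int, int, int]] = []
    attempts = 0
    limit = 10000 * max(spec.n_spots, 1)
    while len(centers) < spec.n_spots:
        attempts += 1
        if attempts > limit:
            raise ConfigurationError(
                "could not place non-overlapping spots; roi too crowded"
            )
        r = int(rng.integers(r_min, r_max + 1))
        cx = int(rng.integers(left + r_max, left + w - r_max))
        cy = int(rng.integers(top + r_max, top + h - r_max))
        if all((cx - x) ** 2 + (cy - y) ** 2 >= min_dist2 for x, y, _ in centers):
            centers.append((cx, cy, r))
    return centers


def generate_larva_image(spec: ImageSpec) -> tuple[np.ndarray, dict]:
    """Render a dark-spot larval image and its exact pixel ground truth.

    Returns ``(image, truth)`` with an 8-bit grayscale image (rows = y) and
    ``truth = {"n_spots", "area_px", "mask"}``; ``mask`` is the exact
    boolean foreground pixel set.  Spots are noise-free discs at
    ``spot_intensity``; the background carries Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), float(spec.background_intensity))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    mask = np.zeros(img.shape, dtype=bool)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    for cx, cy, r in _place_spots(spec, rng):
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        mask |= disc
    img[mask] = spec.spot_intensity
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, {"n_spots": spec.n_spots, "area_px": int(mask.sum()), "mask": mask}


def generate_spheroid_image(
    width: int = 512,
    height: int = 512,
    radius: int = 50,
    center: tuple[int, int] | None = None,
    spot_intensity: int = 60,
    background_intensity: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Single dark disc (a spheroid core) on a light background."""
    cx, cy = center or (width // 2, height // 2)
    if not (radius <= cx < width - radius and radius <= cy < height - radius):
        raise ConfigurationError("spheroid disc extends outside the image")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), float(background_intensity))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    yy, xx = np.mgrid[0:height, 0:width]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius * radius] = spot_intensity
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_fold_experiments(
    n_experiments: int = 6,
    wells_per_group: int = 8,
    cv: float = 0.05,
    casper_mean: float = 0.05,
    wt_mean: float = 0.35,
    v12ras_mean: float = 0.479,
    seed: int = 0,
) -> pd.DataFrame:
    """Background-subtracted well values for repeated fold-change experiments.

    Per-well multiplicative noise with coefficient of variation ``cv`` on
    the true subtracted means (wt - casper) and (v12ras - casper).  Returns
    a long table (experiment, group in {wt, v12ras}, subtracted_value).
    """
    rng = np.random.default_rng(seed)
    wt_sub = wt_mean - casper_mean
    tg_sub = v12ras_mean - casper_mean
    rows = []
    for exp in range(1, n_experiments + 1):
        for group, mean in (("wt", wt_sub), ("v12ras", tg_sub)):
            vals = mean * (1.0 + rng.normal(0.0, cv, size=wells_per_group))
            rows.extend(
                {"experiment": exp, "group": group, "subtracted_value": float(v)}
                for v in vals
            )
    return pd.DataFrame(rows, columns=["experiment", "group", "subtracted_value"])
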