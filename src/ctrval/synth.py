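"""Synthetic study generator: every input the validation pipeline needs.

Because chest-radiograph datasets with multi-reader CTR measurements are
rarely shareable, the pipeline is exercised end-to-end on synthetic data
that mirrors the structure of a real validation study:

* a case population with a truncated-normal CTR distribution (mean 0.522,
  SD 0.095) stratified into four pathology categories of 40 cases each
  (normal, pneumothorax, pleural effusion, consolidation);
* expert annotators (2 radiologists x 2 sessions), reader annotators
  (5 radiologists x 1 session) and an automatic model, each measuring
  every case with observer-specific bias, session drift and per-measurement
  noise, inflated in the effusion/consolidation strata where anatomy
  obscures the relevant borders;
* rasterized lung/heart mask pairs whose analytic CTR is known, with
  stylized pathology perturbations (apex collapse, basal blunting with
  optional lateral clipping of the costophrenic angle, medial blob
  erosion);
* binary label matrices drawn from known annotator confusion matrices.

All generators are deterministic given their seed; the default calibration
lives in ``ctrval/data/default_study.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .consensus import LabelMatrix
from .errors import InfeasibleGeometryError, InvalidConfusionError
from .geometry import MaskPair

__all__ = [
    "CATEGORIES",
    "PopulationSpec",
    "ObserverSpec",
    "StudyData",
    "default_config",
    "default_population_spec",
    "default_observer_spec",
    "simulate_population",
    "simulate_measurements",
    "simulate_masks",
    "simulate_labelers",
    "simulate_study",
]

CATEGORIES = ("normal", "pneumothorax", "effusion", "consolidation")


def default_config() -> dict:
    """The packaged default study calibration (parsed YAML)."""
    text = resources.files("ctrval.data").joinpath("default_study.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class PopulationSpec:
    """Case population: CTR distribution, pathology strata, case difficulty.

    ``difficulty_log_sd`` controls a per-case lognormal noise multiplier
    shared by every observer (hard films are hard for everyone): a few
    cases dominate the disagreement, as in real reading studies, which is
    what gives agreement statistics their realistic sampling spread.  The
    multiplier is normalized to unit mean square, so it changes the shape
    of the error distribution but not the average noise power.
    """

    n_per_category: int = 40
    ctr_mean: float = 0.522
    ctr_sd: float = 0.095
    ctr_bounds: tuple[float, float] = (0.2, 0.9)
    difficulty_log_sd: float = 0.25
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if self.n_per_category < 1:
            raise ValueError("n_per_category must be >= 1")
        if self.difficulty_log_sd < 0:
            raise ValueError("difficulty_log_sd must be non-negative")
        lo, hi = self.ctr_bounds
        if not (0 < lo < hi <= 1.5):
            raise ValueError("ctr_bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class ObserverSpec:
    """Observer noise model for one group of annotators.

    A measurement of case i by observer o in session s is

        ctr_obs = ctr_true + b_o + u_{o,s} + m(category) * d_i * e

    with b_o a stable observer offset, u_{o,s} ~ N(0, session_sd^2) a
    session-level drift, e ~ N(0, within_sd^2) the per-measurement noise,
    m(category) >= 1 the stratum noise multiplier, and d_i the case's
    difficulty multiplier.  Observed CTRs are truncated to (0.1, 1.0).

    Observer offsets are calibration constants, not noise: by default they
    come from ``bias_offsets`` (one entry per observer, added to
    ``bias_mean``), so repeated studies describe the same panel of
    observers.  When ``bias_offsets`` is None the offsets are drawn
    N(0, bias_sd^2) once per observer instead.
    """

    role: str
    n_observers: int
    n_sessions: int = 1
    bias_mean: float = 0.0
    bias_offsets: tuple[float, ...] | None = None
    bias_sd: float = 0.0
    session_sd: float = 0.0
    within_sd: float = 0.0
    category_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.bias_sd, self.session_sd, self.within_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.bias_offsets is not None:
            object.__setattr__(self, "bias_offsets", tuple(self.bias_offsets))
            if len(self.bias_offsets) != self.n_observers:
                raise ValueError("bias_offsets must have one entry per observer")
        if any(m < 0 for m in self.category_multipliers.values()):
            raise ValueError("category multipliers must be non-negative")

    def multiplier(self, category: str) -> float:
        return float(self.category_multipliers.get(category, 1.0))


def default_population_spec() -> PopulationSpec:
    cfg = default_config()["population"]
    return PopulationSpec(
        n_per_category=cfg["n_per_category"],
        ctr_mean=cfg["ctr_mean"],
        ctr_sd=cfg["ctr_sd"],
        ctr_bounds=tuple(cfg["ctr_bounds"]),
        difficulty_log_sd=cfg.get("difficulty_log_sd", 0.25),
    )


def default_observer_spec(role: str) -> ObserverSpec:
    """Packaged defaults for ``role`` in {'experts', 'readers', 'model'}."""
    cfg = default_config()["observers"][role]
    offsets = cfg.get("bias_offsets")
    return ObserverSpec(
        role=role.rstrip("s") if role != "model" else "model",
        n_observers=cfg["n_observers"],
        n_sessions=cfg["n_sessions"],
        bias_mean=cfg["bias_mean"],
        bias_offsets=tuple(offsets) if offsets is not None else None,
        bias_sd=cfg.get("bias_sd", 0.0),
        session_sd=cfg["session_sd"],
        within_sd=cfg["within_sd"],
        category_multipliers=dict(cfg["category_multipliers"]),
    )


def simulate_population(
    spec: PopulationSpec = PopulationSpec(), seed: int | None = None
) -> pd.DataFrame:
    """Case table: case_id, pathology_category, true_ctr, gt_px.

    True CTRs are truncated-normal draws; GT (thoracic width in pixels) is
    fixed per case and used only to back-fill consistent MLD/MRD/GT columns
    in the measurement tables.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.ctr_bounds
    a = (lo - spec.ctr_mean) / spec.ctr_sd
    b = (hi - spec.ctr_mean) / spec.ctr_sd
    n_total = spec.n_per_category * len(spec.categories)
    ctr = stats.truncnorm.rvs(
        a, b, loc=spec.ctr_mean, scale=spec.ctr_sd, size=n_total, random_state=rng
    )
    gt = np.clip(np.round(rng.normal(280, 20, size=n_total)), 180, 400).astype(int)
    tau = spec.difficulty_log_sd
    difficulty = np.exp(rng.normal(0.0, tau, size=n_total) - tau**2)  # E[d^2] = 1
    width = len(str(n_total))
    return pd.DataFrame(
        {
            "case_id": [f"case{idx:0{width}d}" for idx in range(1, n_total + 1)],
            "pathology_category": np.repeat(spec.categories, spec.n_per_category),
            "true_ctr": ctr,
            "gt_px": gt,
            "difficulty": difficulty,
        }
    )


def simulate_measurements(
    cases: pd.DataFrame,
    observers: ObserverSpec,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long measurement table for one observer group.

    Columns: case_id, annotator_id, role, session, mld, mrd, gt, ctr,
    pathology_category.  MLD/MRD/GT are back-filled consistently with the
    observed CTR: GT is the case's fixed thoracic width and the heart span
    splits roughly 60:40 (left:right) with jitter.
    """
    rng = np.random.default_rng(seed)
    n = len(cases)
    true_ctr = cases["true_ctr"].to_numpy()
    gt = cases["gt_px"].to_numpy(dtype=float)
    mult = np.array([observers.multiplier(c) for c in cases["pathology_category"]])
    if "difficulty" in cases.columns:
        mult = mult * cases["difficulty"].to_numpy(dtype=float)
    rows = []
    for o in range(observers.n_observers):
        annotator = f"{observers.role}{o + 1}"
        if observers.bias_offsets is not None:
            bias = observers.bias_mean + observers.bias_offsets[o]
        else:
            bias = observers.bias_mean + rng.normal(0.0, observers.bias_sd)
        for s in range(1, observers.n_sessions + 1):
            drift = rng.normal(0.0, observers.session_sd)
            noise = rng.normal(0.0, 1.0, size=n) * observers.within_sd * mult
            ctr = np.clip(true_ctr + bias + drift + noise, 0.1, 1.0)
            span = ctr * gt
            split = 0.6 + rng.uniform(-0.05, 0.05, size=n)
            mld = span * split
            rows.append(
                pd.DataFrame(
                    {
                        "case_id": cases["case_id"].to_numpy(),
                        "annotator_id": annotator,
                        "role": observers.role,
                        "session": s,
                        "mld": mld,
                        "mrd": span - mld,
                        "gt": gt,
                        "ctr": ctr,
                        "pathology_category": cases["pathology_category"].to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Mask synthesis
# ---------------------------------------------------------------------------

def _ellipse(shape, rc, cc, rb, cb) -> np.ndarray:
    rr, cols = np.ogrid[: shape[0], : shape[1]]
    return ((cols - cc) / cb) ** 2 + ((rr - rc) / rb) ** 2 <= 1.0


def simulate_masks(
    true_ctr: float,
    image_size: tuple[int, int] = (512, 512),
    category: str = "normal",
    seed: int | None = None,
    effusion_lateral_clip: float = 0.0,
) -> tuple[MaskPair, dict]:
    """Rasterized thorax: two half-ellipse lung fields and an elliptical heart.

    The heart's column span is chosen so that the analytic
    ``(MLD + MRD) / GT`` equals ``true_ctr`` to within rounding (< 1/GT);
    the returned dict carries the analytic mld/mrd/gt/ctr of the intended
    anatomy.  Pathology categories perturb the lung mask only in ways that
    mirror the direction of real measurement biases:

    * pneumothorax — one lung apex collapses (rows above the upper third
      removed); lateral extremes sit at mid-height, so GT is unchanged;
    * effusion — one lung base is truncated and, if
      ``effusion_lateral_clip`` > 0, that lung's lateral edge is clipped by
      the given fraction of GT, shrinking the measured thoracic width (the
      measured CTR then exceeds the analytic one);
    * consolidation — blob erosions along the heart-adjacent border of one
      lung (texture change; extremes untouched).
    """
    h_img, w_img = image_size
    if h_img < 128 or w_img < 128:
        raise InfeasibleGeometryError("infeasible-geometry: image must be >= 128x128")
    if not (0 < true_ctr):
        raise InfeasibleGeometryError("infeasible-geometry: CTR must be positive")
    rng = np.random.default_rng(seed)

    m = w_img // 2                      # intended midline column
    half = int(0.40 * w_img)            # thorax half-width
    left_col, right_col = m - half, m + half
    gt = 2 * half + 1
    span = int(round(true_ctr * gt))    # MLD + MRD in pixels
    if span < 1:
        raise InfeasibleGeometryError("infeasible-geometry: heart narrower than 1 px")
    split = 0.6 + rng.uniform(-0.05, 0.05)
    mld = int(round(span * split))
    mld = min(max(mld, 0), span)
    mrd = span - mld
    heart_left, heart_right = m - mrd, m + mld
    if heart_left < 0 or heart_right > w_img - 1:
        raise InfeasibleGeometryError(
            f"infeasible-geometry: CTR {true_ctr:.3f} does not fit a "
            f"{w_img}-px-wide image"
        )

    r_mid = int(0.5 * h_img)
    lung_rb = 0.32 * h_img
    gap = 8                             # medial gap between lung and midline
    if half <= gap + 4:
        raise InfeasibleGeometryError("infeasible-geometry: thorax too narrow")

    def lung(c_out, c_in):
        cc = (c_out + c_in) / 2.0
        cb = abs(c_in - c_out) / 2.0
        return _ellipse(image_size, r_mid, cc, lung_rb, cb)

    left_lung = lung(left_col, m - gap)
    right_lung = lung(right_col, m + gap)

    rr = np.arange(h_img)[:, None]
    side = rng.integers(0, 2)  # 0 = patient-right (image-left) lung
    target = left_lung if side == 0 else right_lung
    if category == "pneumothorax":
        target &= ~(rr < r_mid - 0.25 * lung_rb)
    elif category == "effusion":
        target &= ~(rr > r_mid + 0.30 * lung_rb)
        if effusion_lateral_clip > 0:
            clip = int(round(effusion_lateral_clip * gt))
            cols = np.arange(w_img)[None, :]
            if side == 0:
                target &= ~(cols < left_col + clip)
            else:
                target &= ~(cols > right_col - clip)
    elif category == "consolidation":
        inner = m - gap if side == 0 else m + gap
        for _ in range(rng.integers(3, 7)):
            br = rng.integers(r_mid - int(lung_rb * 0.6), r_mid + int(lung_rb * 0.6))
            radius = rng.integers(4, 9)
            offset = rng.integers(0, int(half * 0.3))
            bc = inner + offset if side == 0 else inner - offset
            # carve a blob from the medial border; lateral extremes untouched
            target &= ~_ellipse(image_size, br, bc, radius, radius)
    elif category != "normal":
        raise ValueError(f"unknown category {category!r}")
    if side == 0:
        left_lung = target
    else:
        right_lung = target

    # integer heart-center row so one raster row realizes the full span
    heart = _ellipse(
        image_size,
        int(round(r_mid + 0.08 * h_img)),
        (heart_left + heart_right) / 2.0,
        0.20 * h_img,
        max((heart_right - heart_left) / 2.0, 0.5),
    )
    pair = MaskPair(lung=left_lung | right_lung, heart=heart)
    analytic = {
        "mld": mld,
        "mrd": mrd,
        "gt": gt,
        "ctr": span / gt,
        "requested_ctr": float(true_ctr),
        "midline_col": m,
    }
    return pair, analytic


def simulate_labelers(
    true_labels,
    confusions,
    seed: int | None = None,
    set_ids: list | None = None,
    case_ids: list | None = None,
) -> LabelMatrix:
    """Draw one binary label matrix from per-set confusion matrices.

    ``confusions`` is a sequence of 2x2 row-stochastic matrices
    (row = true class, column = emitted label); each set's label for a case
    is drawn from its confusion row given the hidden true label.
    """
    truth = np.asarray(true_labels, dtype=int)
    conf = np.asarray(confusions, dtype=float)
    if conf.ndim != 3 or conf.shape[1:] != (2, 2):
        raise InvalidConfusionError("invalid-confusion: need a stack of 2x2 matrices")
    if (conf < 0).any() or not np.allclose(conf.sum(axis=2), 1.0):
        raise InvalidConfusionError("invalid-confusion: rows must sum to 1")
    rng = np.random.default_rng(seed)
    n, m = truth.size, conf.shape[0]
    p_emit_1 = conf[:, :, 1]  # per set: P(label 1 | true class)
    labels = (rng.random((n, m)) < p_emit_1[:, truth].T).astype(int)
    return LabelMatrix(
        labels=labels,
        set_ids=set_ids if set_ids is not None else [f"set{j + 1}" for j in range(m)],
        case_ids=case_ids if case_ids is not None else list(range(n)),
    )


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyData:
    """All tables of one synthetic validation study."""

    cases: pd.DataFrame
    expert_measurements: pd.DataFrame
    reader_measurements: pd.DataFrame
    model_measurements: pd.DataFrame
    seed: int | None

    @property
    def measurements(self) -> pd.DataFrame:
        """Experts and readers in one long table (the pipeline input)."""
        return pd.concat(
            [self.expert_measurements, self.reader_measurements], ignore_index=True
        )


def simulate_study(
    seed: int,
    population: PopulationSpec | None = None,
    experts: ObserverSpec | None = None,
    readers: ObserverSpec | None = None,
    model: ObserverSpec | None = None,
) -> StudyData:
    """Generate a complete study under the default (or given) calibration.

    A single master seed drives four independent child streams (population,
    experts, readers, model), so any fixed seed reproduces the study
    byte-for-byte.
    """
    population = population or default_population_spec()
    experts = experts or default_observer_spec("experts")
    readers = readers or default_observer_spec("readers")
    model = model or default_observer_spec("model")
    model = replace(model, role="model")
    ss = np.random.SeedSequence(seed)
    s_pop, s_exp, s_read, s_model = ss.spawn(4)
    cases = simulate_population(population, seed=s_pop)
    return StudyData(
        cases=cases,
        expert_measurements=simulate_measurements(cases, experts, seed=s_exp),
        reader_measurements=simulate_measurements(cases, readers, seed=s_read),
        model_measurements=simulate_measurements(cases, model, seed=s_model),
        seed=seed,
    )
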