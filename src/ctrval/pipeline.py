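"""End-to-end study orchestration and report generation.

``run_study`` executes the whole validation pipeline in order —
simulate (or ingest) → measure → agreement → consensus → reader test →
reports — and writes the study's standard outputs to a directory:

* ``table1.csv``   Bland–Altman strata (absolute and relative scales,
  LOAs with CIs, MAE/RMSE), model versus the expert mean;
* ``table2.csv``   ICC grid: intra-observer, expert–expert inter-observer
  and model-versus-experts, with the bootstrap p for the inter-ICC
  comparison, overall and per stratum;
* ``table3.csv``   diagnostic grid (overall + subgroups x 5 metrics) with
  one-sided non-inferiority p-values, Dawid–Skene reference at the primary
  cutoff;
* ``appendix.csv`` the same grid at the secondary cutoff and with the
  median reference;
* ``reference_<cutoff>.csv/.json``  per-case consensus posteriors and the
  fitted annotator confusion matrices;
* ``audit.csv``    per-case trace (model CTR, reader CTR range, posterior);
* ``bland_altman_absolute.png`` / ``bland_altman_relative.png``;
* ``provenance.json``  stage log with seeds and input content hashes.

The reference standard is built exclusively from the expert annotation
sets; the provenance log records the annotator ids that entered consensus
construction so the firewall against reader/model leakage is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import consensus as cns
from . import reader_test as rt
from . import synth
from .geometry import measure_directory

__all__ = ["StudyConfig", "run_study"]

_FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """Configuration of one study run.

    ``mode='synthetic'`` generates the study from the packaged calibration;
    ``mode='files'`` ingests a long measurement CSV (expert + reader rows,
    ``role`` column) and either a model CSV or a directory of mask pairs.
    """

    seed: int
    mode: str = "synthetic"
    measurements_csv: str | None = None
    model_csv: str | None = None
    masks_dir: str | None = None
    cutoffs: tuple[float, float] = (0.50, 0.55)
    reference_modes: tuple[str, ...] = ("dawid-skene", "median")
    margin: float = 0.10
    n_boot_icc: int = 1000
    n_boot_noninferiority: int = 2000
    subgroups: list[str] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if not all(0 < c < 1 for c in self.cutoffs):
            raise ValueError("cutoffs must lie in (0, 1)")
        if self.mode == "files":
            if self.measurements_csv is None:
                raise ValueError("files mode requires measurements_csv")
            if self.model_csv is None and self.masks_dir is None:
                raise ValueError("files mode requires model_csv or masks_dir")
            for p in (self.measurements_csv, self.model_csv, self.masks_dir):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {
            k: raw[k]
            for k in (
                "seed",
                "mode",
                "measurements_csv",
                "model_csv",
                "masks_dir",
                "margin",
                "n_boot_icc",
                "n_boot_noninferiority",
                "subgroups",
            )
            if k in raw
        }
        if "cutoffs" in raw:
            known["cutoffs"] = tuple(raw["cutoffs"])
        if "reference_modes" in raw:
            known["reference_modes"] = tuple(raw["reference_modes"])
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**known, extra=extra)


def _sha256(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format=_FLOAT_FMT).encode()
    ).hexdigest()


def _child_seeds(master: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def _bland_altman_table(expert_meas, model_meas, categories) -> pd.DataFrame:
    rows = []
    for stratum in ["overall", *categories]:
        if stratum == "overall":
            e, mm = expert_meas, model_meas
        else:
            e = expert_meas[expert_meas["pathology_category"] == stratum]
            cases = e["case_id"].unique()
            mm = model_meas[model_meas["case_id"].isin(cases)]
        for scale in ("absolute", "relative"):
            pairs = agr.model_vs_experts_pairs(e, mm, scale=scale)
            res = agr.bland_altman(pairs)
            mae, rmse = agr.mae_rmse(pairs) if scale == "absolute" else (np.nan, np.nan)
            rows.append(
                {
                    "stratum": stratum,
                    "scale": scale,
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                    "sd_diff": res.sd_diff,
                    "loa_lower": res.loa_lower,
                    "loa_lower_ci_lo": res.loa_lower_ci[0],
                    "loa_lower_ci_hi": res.loa_lower_ci[1],
                    "loa_upper": res.loa_upper,
                    "loa_upper_ci_lo": res.loa_upper_ci[0],
                    "loa_upper_ci_hi": res.loa_upper_ci[1],
                    "mae": mae,
                    "rmse": rmse,
                }
            )
    return pd.DataFrame(rows)


def _icc_table(expert_meas, model_meas, categories, n_boot, seeds) -> pd.DataFrame:
    rows = []
    experts = sorted(expert_meas["annotator_id"].unique())
    for annotator in experts:
        res = agr.icc(agr.intra_observer_matrix(expert_meas, annotator), kind="intra")
        rows.append(
            {
                "comparison": f"intra:{annotator}",
                "stratum": "overall",
                "icc": res.estimate,
                "ci_lo": res.ci[0],
                "ci_hi": res.ci[1],
                "n_cases": res.n_cases,
                "p_bootstrap": np.nan,
            }
        )
    for stratum, seed in zip(["overall", *categories], seeds):
        if stratum == "overall":
            e, mm = expert_meas, model_meas
        else:
            e = expert_meas[expert_meas["pathology_category"] == stratum]
            mm = model_meas[model_meas["case_id"].isin(e["case_id"].unique())]
        rad = agr.expert_session_means(e)
        stacked = agr.model_vs_experts_stacked_matrix(e, mm)
        res_rad = agr.icc(rad, kind="inter")
        res_mod = agr.icc(stacked, kind="inter")
        cmp_res = agr.compare_icc_bootstrap(rad, stacked, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "comparison": "inter:radiologists",
                "stratum": stratum,
                "icc": res_rad.estimate,
                "ci_lo": res_rad.ci[0],
                "ci_hi": res_rad.ci[1],
                "n_cases": res_rad.n_cases,
                "p_bootstrap": np.nan,
            }
        )
        rows.append(
            {
                "comparison": "inter:model-vs-radiologists",
                "stratum": stratum,
                "icc": res_mod.estimate,
                "ci_lo": res_mod.ci[0],
                "ci_hi": res_mod.ci[1],
                "n_cases": len(rad),
                "p_bootstrap": cmp_res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _ba_plot(pairs: agr.PairedSeries, res: agr.AgreementResult, path: Path, title: str):
    d = pairs.differences()
    means = (pairs.x + pairs.y) / 2.0
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(means, d, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(res.mean_diff, color="tab:red", lw=1.2, label="mean difference")
    for loa, ci in (
        (res.loa_lower, res.loa_lower_ci),
        (res.loa_upper, res.loa_upper_ci),
    ):
        ax.axhline(loa, color="tab:blue", ls="--", lw=1.4)
        ax.axhspan(ci[0], ci[1], color="tab:blue", alpha=0.15)
    ax.set_xlabel("mean of paired CTR measurements")
    ax.set_ylabel(
        "difference (model - experts)"
        + (" [%]" if pairs.scale == "relative" else "")
    )
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns a dict of output paths.

    Any stage failure propagates with the stage name prefixed to the
    message (the CLI turns that into a non-zero exit).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 16)
    provenance: list[dict] = []
    paths: dict[str, str] = {}

    def log(stage: str, **info):
        provenance.append({"stage": stage, **info})

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc

    # -- stage: data -------------------------------------------------------
    def _data():
        if config.mode == "synthetic":
            study = synth.simulate_study(seed=seeds[0])
            meas, model = study.measurements, study.model_measurements
            model = model[["case_id", "ctr"]].copy()
        else:
            meas = pd.read_csv(config.measurements_csv)
            if config.masks_dir is not None:
                model = measure_directory(config.masks_dir)[["case_id", "ctr"]]
            else:
                model = pd.read_csv(config.model_csv)[["case_id", "ctr"]]
        log("data", seed=seeds[0], mode=config.mode,
            measurements_sha256=_sha256(meas), model_sha256=_sha256(model))
        return meas, model

    measurements, model = run_stage("data", _data)
    experts = measurements[measurements["role"] == "expert"]
    categories = sorted(measurements["pathology_category"].dropna().unique())

    # -- stage: agreement --------------------------------------------------
    def _agreement():
        t1 = _bland_altman_table(experts, model, categories)
        t2 = _icc_table(
            experts, model, categories, config.n_boot_icc, seeds[1:1 + 1 + len(categories)]
        )
        p1, p2 = out / "table1.csv", out / "table2.csv"
        t1.to_csv(p1, index=False, float_format=_FLOAT_FMT)
        t2.to_csv(p2, index=False, float_format=_FLOAT_FMT)
        for scale in ("absolute", "relative"):
            pairs = agr.model_vs_experts_pairs(experts, model, scale=scale)
            res = agr.bland_altman(pairs)
            _ba_plot(
                pairs, res, out / f"bland_altman_{scale}.png",
                f"Model vs thoracic radiologists ({scale})",
            )
        log("agreement", n_boot=config.n_boot_icc, table1=p1.name, table2=p2.name)
        return t1, t2

    table1, table2 = run_stage("agreement", _agreement)

    # -- stage: consensus --------------------------------------------------
    def _consensus():
        refs = {}
        expert_ids = sorted(experts["annotator_id"].unique())
        for cutoff in config.cutoffs:
            lm = cns.LabelMatrix.from_measurements(experts, cutoff=cutoff)
            result = cns.dawid_skene(lm)
            ref = pd.DataFrame(
                {
                    "case_id": result.case_ids,
                    "posterior": result.posterior,
                    "label": result.hard_labels,
                }
            )
            tag = f"{cutoff:.2f}".replace(".", "")
            ref_path = out / f"reference_{tag}.csv"
            ref.to_csv(ref_path, index=False, float_format=_FLOAT_FMT)
            sidecar = {
                "cutoff": cutoff,
                "prior": result.prior,
                "n_iter": result.n_iter,
                "converged": result.converged,
                "annotation_sets": result.set_ids,
                "confusion": result.confusion.tolist(),
            }
            with open(out / f"reference_{tag}.json", "w") as fh:
                json.dump(sidecar, fh, indent=1, sort_keys=True)
            refs[cutoff] = ref.set_index("case_id")
            paths[f"reference_{tag}"] = str(ref_path)
        log(
            "consensus",
            cutoffs=list(config.cutoffs),
            annotation_sets_used=expert_ids,
            roles_used=["expert"],  # firewall: never readers or the model
        )
        return refs

    references = run_stage("consensus", _consensus)

    # -- stage: readertest -------------------------------------------------
    def _readertest():
        primary, secondary = config.cutoffs
        t3 = rt.run_reader_study(
            measurements, model, cutoff=primary, reference_mode="dawid-skene",
            margin=config.margin, n_boot=config.n_boot_noninferiority, seed=seeds[8],
        )
        appendix_parts = []
        if "dawid-skene" in config.reference_modes:
            app1 = rt.run_reader_study(
                measurements, model, cutoff=secondary, reference_mode="dawid-skene",
                margin=config.margin, n_boot=config.n_boot_noninferiority,
                seed=seeds[9],
            )
            app1.insert(0, "analysis", f"dawid-skene@{secondary}")
            appendix_parts.append(app1)
        if "median" in config.reference_modes:
            app2 = rt.run_reader_study(
                measurements, model, cutoff=primary, reference_mode="median",
                margin=config.margin, n_boot=config.n_boot_noninferiority,
                seed=seeds[10],
            )
            app2.insert(0, "analysis", f"median@{primary}")
            appendix_parts.append(app2)
        p3, pa = out / "table3.csv", out / "appendix.csv"
        t3.to_csv(p3, index=False, float_format=_FLOAT_FMT)
        pd.concat(appendix_parts, ignore_index=True).to_csv(
            pa, index=False, float_format=_FLOAT_FMT
        )
        log("readertest", seed=seeds[8], margin=config.margin,
            n_boot=config.n_boot_noninferiority, table3=p3.name, appendix=pa.name)
        return t3

    table3 = run_stage("readertest", _readertest)

    # -- stage: audit ------------------------------------------------------
    def _audit():
        readers = measurements[measurements["role"] == "reader"]
        reader_rng = readers.groupby("case_id")["ctr"].agg(["min", "max"])
        model_s = model.set_index("case_id")["ctr"]
        ref = references[config.cutoffs[0]]
        audit = pd.DataFrame(
            {
                "case_id": ref.index,
                "model_ctr": model_s.reindex(ref.index).to_numpy(),
                "reader_ctr_min": reader_rng["min"].reindex(ref.index).to_numpy(),
                "reader_ctr_max": reader_rng["max"].reindex(ref.index).to_numpy(),
                "reference_posterior": ref["posterior"].to_numpy(),
                "reference_label": ref["label"].to_numpy(),
            }
        )
        p = out / "audit.csv"
        audit.to_csv(p, index=False, float_format=_FLOAT_FMT)
        log("audit", audit=p.name)

    run_stage("audit", _audit)

    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {"master_seed": config.seed, "stages": provenance}, fh, indent=1,
            sort_keys=True,
        )

    paths.update(
        {
            "table1": str(out / "table1.csv"),
            "table2": str(out / "table2.csv"),
            "table3": str(out / "table3.csv"),
            "appendix": str(out / "appendix.csv"),
            "audit": str(out / "audit.csv"),
            "provenance": str(out / "provenance.json"),
        }
    )
    return paths
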