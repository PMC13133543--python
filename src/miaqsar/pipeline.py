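"""End-to-end study orchestration.

``run_study`` reproduces the whole modeling protocol for each configured
pixel property: encode the series, screen the applicability domain on the
full dataset (Williams plot), split by Kennard-Stone (75/25), select the
latent-variable count by leave-one-out, fit, compute calibration /
cross-validation / external statistics, y-randomization, random test-set
(bootstrap) stability cycles, interpretation maps, and finally predict the
proposed analogs with the per-property models refit on all data, averaging
the two property models' predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import pls_engine, sampling, validation_suite
from .chem_model import CompoundSpec, TemplateLibrary, load_template_library
from .datasets import load_compound_table, load_proposals, specs_from_table
from .interpretation import export_heatmap, fold_map
from .mia_encoder import DescriptorMatrix, build_descriptor_matrix, default_canvas
from .validation_suite import ADReport, MetricsReport

log = logging.getLogger("miaqsar")

__all__ = ["RunConfig", "PropertyStudy", "StudyReport", "run_study", "predict_proposals"]

PROPERTIES = ("vdw_radius", "electronegativity")

# metrics averaged over bootstrap cycles (matches the per-model report block)
_BOOT_KEYS = (
    "A", "rmsec", "r2", "rmse_yrand", "r2_yrand", "c_r2p", "rmsecv", "q2",
    "rmsep", "r2_pred", "r2m_test", "avg_r2m", "delta_r2m", "ccc",
    "q2_f1", "q2_f2", "mae",
)


@dataclass
class RunConfig:
    """Study settings; the defaults are the study conditions."""

    dataset: str | None = None  # packaged 33-compound fixture when None
    proposals: str | None = None  # packaged 8 analogs when None
    properties: tuple[str, ...] = PROPERTIES
    canvas_width: int = 300
    canvas_height: int = 348
    train_fraction: float = 0.75
    n_yrand: int = 10
    n_bootstrap: int = 10
    a_max: int = 15
    seed: int = 20260
    paint_bonds: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.properties:
            raise ValueError("at least one property must be modeled")
        for p in self.properties:
            if p not in PROPERTIES:
                raise ValueError(f"unknown property {p!r}; choose from {PROPERTIES}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "properties" in data:
            data["properties"] = tuple(data["properties"])
        data.update(overrides)
        return cls(**data)


@dataclass
class PropertyStudy:
    """Everything computed for one pixel property."""

    property_kind: str
    metrics: MetricsReport
    bootstrap_mean: dict[str, float]
    bootstrap_sd: dict[str, float]
    ad: ADReport
    split_train: list[str]
    split_test: list[str]
    p_retained: int
    calibration: pd.DataFrame  # id, role, observed, predicted

    def to_dict(self) -> dict:
        return {
            "property_kind": self.property_kind,
            "metrics": self.metrics.to_dict(),
            "bootstrap_mean": self.bootstrap_mean,
            "bootstrap_sd": self.bootstrap_sd,
            "ad": self.ad.to_dict(),
            "split_train": self.split_train,
            "split_test": self.split_test,
            "p_retained": self.p_retained,
            "calibration": self.calibration.to_dict(orient="list"),
        }


@dataclass
class StudyReport:
    config: RunConfig
    properties: dict[str, PropertyStudy]
    proposals: pd.DataFrame  # id, per-model predictions, average, leverage flag

    def to_dict(self) -> dict:
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        return {
            "config": cfg,
            "properties": {k: v.to_dict() for k, v in self.properties.items()},
            "proposals": self.proposals.to_dict(orient="list"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _metric_suite(
    Xm: np.ndarray,
    y: np.ndarray,
    plan: sampling.SplitPlan,
    a_max: int,
    n_yrand: int,
    yrand_seed: int,
) -> tuple[MetricsReport, pls_engine.PLSModel]:
    """Calibrate on the plan's training rows and compute the full block."""
    tr, te = list(plan.train), list(plan.test)
    Xtr, ytr, Xte, yte = Xm[tr], y[tr], Xm[te], y[te]
    A = pls_engine.select_components(Xtr, ytr, min(len(tr) - 2, a_max))
    model = pls_engine.fit(Xtr, ytr, A, allow_fewer=True)
    rmsec, r2 = validation_suite.calibration_metrics(ytr, model.fitted)
    rmsecv, q2 = validation_suite.cross_validation(Xtr, ytr, model.A)
    ext = validation_suite.external_metrics(
        yte, pls_engine.predict(model, Xte), float(ytr.mean())
    )
    r2s, rmses = [], []
    for yp in sampling.y_randomize(ytr, n_yrand, yrand_seed):
        mp = pls_engine.fit(Xtr, yp, model.A, allow_fewer=True)
        rc, rr = validation_suite.calibration_metrics(yp, mp.fitted)
        rmses.append(rc)
        r2s.append(rr)
    rmse_yr, r2_yr, c_r2p = validation_suite.y_randomization_summary(r2, r2s, rmses)
    report = MetricsReport(
        A=model.A, rmsec=rmsec, r2=r2, rmsecv=rmsecv, q2=q2,
        rmsep=ext["rmsep"], r2_pred=ext["r2_pred"], r2m_test=ext["r2m_test"],
        avg_r2m=ext["avg_r2m"], delta_r2m=ext["delta_r2m"], ccc=ext["ccc"],
        q2_f1=ext["q2_f1"], q2_f2=ext["q2_f2"], mae=ext["mae"],
        rmse_yrand=rmse_yr, r2_yrand=r2_yr, c_r2p=c_r2p,
    )
    return report, model


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full study; deterministic for a fixed config."""
    templates = load_template_library()
    canvas = default_canvas(
        templates, width=config.canvas_width, height=config.canvas_height
    )
    df = load_compound_table(config.dataset)
    specs = specs_from_table(df)
    if df["pic50"].isna().any():
        raise ValueError("every modeled compound needs a pIC50")
    y = df["pic50"].to_numpy(dtype=float)

    seed_root = np.random.SeedSequence(config.seed)
    prop_seeds = seed_root.spawn(len(config.properties))

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    studies: dict[str, PropertyStudy] = {}
    full_models: dict[str, pls_engine.PLSModel] = {}
    matrices: dict[str, DescriptorMatrix] = {}
    for prop, pseed in zip(config.properties, prop_seeds):
        log.info("encoding %s", prop)
        dm = build_descriptor_matrix(
            specs, prop, canvas, templates, paint_bonds=config.paint_bonds
        )
        matrices[prop] = dm
        Xm = dm.masked()

        # applicability-domain screen on the whole dataset
        A_all = pls_engine.select_components(Xm, y, min(len(y) - 2, config.a_max))
        m_all = pls_engine.fit(Xm, y, A_all, allow_fewer=True, column_mask=dm.column_mask)
        ad = validation_suite.williams_domain(m_all, Xm, y, dm.ids)
        if ad.outliers:
            log.warning("%s: applicability-domain outliers: %s", prop, ad.outliers)
        full_models[prop] = m_all

        # representative split + full metric block
        plan = sampling.kennard_stone_split(Xm, config.train_fraction)
        yr_seed, boot_seed = (int(s.generate_state(1)[0] % 2**31)
                              for s in pseed.spawn(2))
        metrics, model = _metric_suite(
            Xm, y, plan, config.a_max, config.n_yrand, yr_seed
        )

        # bootstrap stability cycles (random test-set re-selection)
        boot = {k: [] for k in _BOOT_KEYS}
        plans = sampling.bootstrap_cycles(
            len(y), 1.0 - config.train_fraction, config.n_bootstrap, boot_seed
        )
        for c, bplan in enumerate(plans):
            rep, _ = _metric_suite(
                Xm, y, bplan, config.a_max, config.n_yrand, yr_seed + c + 1
            )
            for k in _BOOT_KEYS:
                boot[k].append(getattr(rep, k))
        boot_mean = {k: float(np.mean(v)) for k, v in boot.items()}
        boot_sd = {k: float(np.std(v, ddof=1)) for k, v in boot.items()}

        pred_all = np.concatenate(
            [model.fitted, pls_engine.predict(model, Xm[list(plan.test)])]
        )
        calib = pd.DataFrame(
            {
                "id": [dm.ids[i] for i in plan.train] + [dm.ids[i] for i in plan.test],
                "role": ["train"] * len(plan.train) + ["test"] * len(plan.test),
                "observed": np.concatenate([y[list(plan.train)], y[list(plan.test)]]),
                "predicted": pred_all,
            }
        )
        studies[prop] = PropertyStudy(
            property_kind=prop,
            metrics=metrics,
            bootstrap_mean=boot_mean,
            bootstrap_sd=boot_sd,
            ad=ad,
            split_train=[dm.ids[i] for i in plan.train],
            split_test=[dm.ids[i] for i in plan.test],
            p_retained=dm.p_retained,
            calibration=calib,
        )

        if outdir:
            vip_map = fold_map(pls_engine.vip(m_all), dm.column_mask, canvas, kind="vip")
            b_map = fold_map(m_all.b, dm.column_mask, canvas, kind="coefficient")
            export_heatmap(vip_map, outdir / f"vip_{prop}.png")
            export_heatmap(b_map, outdir / f"coefficients_{prop}.png")
            calib.to_csv(outdir / f"calibration_{prop}.csv", index=False)

    proposals = predict_proposals(
        full_models, matrices, load_proposals(config.proposals), templates, canvas,
        paint_bonds=config.paint_bonds,
    )
    report = StudyReport(config=config, properties=studies, proposals=proposals)
    if outdir:
        (outdir / "study_report.json").write_text(report.to_json())
        proposals.to_csv(outdir / "proposal_predictions.csv", index=False)
        _write_summary_table(report, outdir / "summary_table.csv")
    return report


def _write_summary_table(report: StudyReport, path: Path) -> None:
    """The statistics block in the study's table layout: one row per metric,
    per-property point value and bootstrap mean +/- sd columns."""
    cols: dict[str, list] = {"parameter": list(_BOOT_KEYS)}
    for prop, st in report.properties.items():
        cols[f"{prop} (K-S)"] = [getattr(st.metrics, k) for k in _BOOT_KEYS]
        cols[f"{prop} (bootstrap)"] = [
            f"{st.bootstrap_mean[k]:.4f} +/- {st.bootstrap_sd[k]:.4f}"
            for k in _BOOT_KEYS
        ]
    pd.DataFrame(cols).to_csv(path, index=False)


def predict_proposals(
    models: dict[str, pls_engine.PLSModel],
    matrices: dict[str, DescriptorMatrix],
    proposal_specs: list[CompoundSpec],
    templates: TemplateLibrary,
    canvas,
    paint_bonds: bool = False,
) -> pd.DataFrame:
    """Predict each proposal with every property model and average.

    Proposals with leverage above a model's h* = 3(A+1)/n are flagged as
    extrapolations.
    """
    from .chem_model import assemble_molecule
    from .mia_encoder import rasterize, unfold

    out: dict[str, list] = {"id": [s.id for s in proposal_specs]}
    per_model = []
    flags = np.zeros(len(proposal_specs), dtype=bool)
    for prop, model in models.items():
        dm = matrices[prop]
        rows = np.stack(
            [
                unfold(rasterize(assemble_molecule(s, templates), prop, canvas,
                                 paint_bonds=paint_bonds))
                for s in proposal_specs
            ]
        )
        rows_masked = rows[:, dm.column_mask]
        preds = pls_engine.predict(model, rows_masked)
        h = pls_engine.leverage(model, rows_masked)
        h_star = 3.0 * (model.A + 1) / model.n_train
        flags |= h > h_star
        out[f"pic50_{prop}"] = [float(v) for v in preds]
        per_model.append(preds)
    out["pic50_avg"] = [float(v) for v in np.mean(per_model, axis=0)]
    out["extrapolation_flag"] = [bool(v) for v in flags]
    return pd.DataFrame(out)
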