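"""End-to-end experiment orchestration.

``run_experiment`` composes the whole workflow: simulate the stress
experiment -> aggregate leaf spectra to pots -> build the two feature
tracks (2151 wavelengths; 32 spectral indices) -> min-max scale ->
70/30 split -> PLS1 component choice and variable selection per metal
-> forward-MLR (with Durbin-Watson / VIF / significance gating) and
grid-tuned epsilon-SVR on the selected features -> R2/RMSE reports.
It also provides the descriptive analyses: per-wavelength correlograms
against each metal and group-mean spectra.

Every random choice derives from one global seed, so two runs with the
same config produce byte-identical report bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import canonical_grid
from .indices import compute_feature_table
from .pls import PLS1, choose_components, select_variables
from .preprocess import MinMaxScaler, SplitSpec, split_train_test
from .regression import (FAST_SVR_GRID, ForwardSelectionMLR, SVRGrid,
                         SVRGridSearch, evaluate)
from .simulate import (METALS, default_design, default_noise,
                       default_response, generate_dataset)
from .spectra import SpectralLibrary, aggregate, write_library_csv

logger = logging.getLogger("vitispec")

__all__ = [
    "ExperimentConfig",
    "ReportBundle",
    "compute_correlogram",
    "mean_spectra_by_group",
    "run_experiment",
]


def compute_correlogram(library: SpectralLibrary, concentrations,
                        metals=None) -> pd.DataFrame:
    """Pearson r between reflectance and concentration, per channel per metal.

    Expects a pot-level library; concentration rows are matched on
    pot_id.  Censored concentrations are excluded pairwise.  Returns a
    DataFrame indexed by wavelength with one column per metal.
    """
    meta = library.metadata
    metals = list(metals) if metals is not None else \
        sorted(concentrations.table["metal"].unique())
    out = {}
    for metal in metals:
        conc = concentrations.for_metal(metal)
        conc = conc[~conc["censored"]]
        pots = [p for p in meta["pot_id"] if p in conc.index]
        if len(pots) < 3:
            raise ValueError(
                f"{metal}: fewer than 3 uncensored pots with spectra")
        idx = meta.index[meta["pot_id"].isin(pots)]
        R = library.reflectance[idx]
        y = conc.loc[meta.loc[idx, "pot_id"], "concentration_mgkg"].to_numpy()
        Rc = R - R.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((Rc ** 2).sum(axis=0) * float(yc @ yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[metal] = (Rc.T @ yc) / denom
    frame = pd.DataFrame(out, index=library.grid.channels)
    frame.index.name = "wavelength_nm"
    return frame


def mean_spectra_by_group(library: SpectralLibrary,
                          grouping: str = "healthy-vs-stressed") -> pd.DataFrame:
    """Channel-wise group-mean spectra.

    ``grouping`` is one of ``healthy-vs-stressed`` (control pots vs all
    dosed pots), ``metal`` or ``level``.  Group sizes are carried in the
    DataFrame ``attrs``.
    """
    meta = library.metadata
    if grouping == "healthy-vs-stressed":
        labels = np.where(meta["level"] == "C", "healthy", "stressed")
    elif grouping == "metal":
        labels = meta["metal"].to_numpy()
    elif grouping == "level":
        labels = meta["level"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out, sizes = {}, {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():  # pragma: no cover
            raise ValueError(f"empty group {g!r}")
        out[str(g)] = library.reflectance[mask].mean(axis=0)
        sizes[str(g)] = int(mask.sum())
    frame = pd.DataFrame(out, index=library.grid.channels)
    frame.index.name = "wavelength_nm"
    frame.attrs["group_sizes"] = sizes
    return frame


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a full run needs; one global seed drives all randomness."""

    seed: int = 0
    metals: tuple[str, ...] = METALS
    tracks: tuple[str, ...] = ("wavelengths", "indices")
    synthetic: dict = field(default_factory=dict)   # DesignSpec/response/noise overrides
    train_fraction: float = 0.7
    stratify_split: bool = True
    scale_before_split: bool = False
    pls_k_max: int = 10
    pls_folds: int = 10
    pls_loading: str = "loadings"   # or "weights"
    mlr_alpha_enter: float = 0.05
    svr_grid: str = "full"          # "full" | "fast"
    svr_folds: int = 10
    model_level: str = "pot"        # "pot" | "leaf"

    def __post_init__(self):
        unknown = set(self.tracks) - {"wavelengths", "indices"}
        if unknown:
            raise ValueError(f"unknown feature tracks: {sorted(unknown)}")
        if self.svr_grid not in ("full", "fast"):
            raise ValueError("svr_grid must be 'full' or 'fast'")
        if self.model_level not in ("pot", "leaf"):
            raise ValueError("model_level must be 'pot' or 'leaf'")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("metals", "tracks"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["metals"] = list(data["metals"])
        data["tracks"] = list(data["tracks"])
        return yaml.safe_dump(data, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _build_generator_parts(config: ExperimentConfig):
    syn = dict(config.synthetic)
    design_kw = {k: syn.pop(k) for k in
                 ("replicates_per_cell", "control_shared", "leaves_per_pot")
                 if k in syn}
    if "levels" in syn:
        design_kw["levels"] = tuple(syn.pop("levels"))
    cr_mal = syn.pop("cr_mal_ugL", 100.0)
    design = default_design(cr_mal_ugL=cr_mal, **design_kw)
    if tuple(config.metals) != METALS:
        design = replace(design, metals=tuple(config.metals),
                         mal_ugL={m: design.mal_ugL[m] for m in config.metals})
    response_kw = {k: syn.pop(k) for k in
                   ("band_amplitude_per_dose", "band_sigma_nm",
                    "broadband_per_dose", "band_gain_cv", "sensitive_bands",
                    "conc_baseline_mgkg", "conc_slope_mgkg") if k in syn}
    response = default_response(**response_kw)
    noise_kw = {k: syn.pop(k) for k in
                ("smooth_sd", "smooth_scale_nm", "uv_blue_sd", "conc_cv",
                 "detection_limits") if k in syn}
    if syn:
        raise ValueError(f"unknown synthetic config keys: {sorted(syn)}")
    noise = default_noise(seed=config.seed, **noise_kw)
    return design, response, noise


@dataclass
class ReportBundle:
    """All artefacts of one experiment run."""

    config: ExperimentConfig
    selection: pd.DataFrame        # per metal x track: k, variances, variables
    models: pd.DataFrame           # per metal x track x method: metrics & gates
    correlogram: pd.DataFrame
    group_means: pd.DataFrame
    library: SpectralLibrary       # pot-level spectra
    concentrations: object

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (f"# vitispec run seed={self.config.seed} "
                  f"config_hash={self.config.config_hash()}\n")

        def _write(frame: pd.DataFrame, name: str, index=False):
            path = outdir / name
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(header)
                frame.to_csv(fh, index=index, float_format="%.6g",
                             lineterminator="\n")

        _write(self.selection, "selection_report.csv")
        _write(self.models, "model_reports.csv")
        _write(self.correlogram.reset_index(), "correlogram.csv")
        _write(self.group_means.reset_index(), "group_mean_spectra.csv")
        write_library_csv(self.library, outdir / "pot_spectra.csv")
        self.concentrations.to_csv(outdir / "concentrations.csv")
        (outdir / "config.yaml").write_text(self.config.to_yaml(),
                                            encoding="utf-8")
        records = self.models.to_dict(orient="records")
        (outdir / "model_reports.json").write_text(
            json.dumps({"seed": self.config.seed,
                        "config_hash": self.config.config_hash(),
                        "models": records}, indent=2, allow_nan=True),
            encoding="utf-8")


def run_experiment(config: ExperimentConfig | None = None) -> ReportBundle:
    """Run the full pipeline and return the report bundle.

    Per metal and feature track: choose the PLS component count by
    RMSECV on the training split, select one variable per component by
    max |factor load|, then fit forward-MLR and grid-tuned SVR on the
    selected features and evaluate both on train and test.
    """
    config = config or ExperimentConfig()
    design, response, noise = _build_generator_parts(config)

    logger.info("simulating: %d pots, %d leaf spectra, %d channels",
                design.n_pots, design.n_spectra, len(canonical_grid()))
    library, concentrations = generate_dataset(design, response, noise)
    pots = aggregate(library, "pot")
    data = pots if config.model_level == "pot" else library
    logger.info("modelling at %s level: n=%d", config.model_level, len(data))

    feature_tracks: dict[str, pd.DataFrame] = {}
    if "wavelengths" in config.tracks:
        cols = [f"R{ch:g}" for ch in data.grid.channels]
        feature_tracks["wavelengths"] = pd.DataFrame(
            data.reflectance, index=data.metadata["sample_id"], columns=cols)
    if "indices" in config.tracks:
        feature_tracks["indices"] = compute_feature_table(data)
    logger.info("feature tracks: %s",
                {k: v.shape for k, v in feature_tracks.items()})

    meta = data.metadata.set_index("sample_id")
    train_ids, test_ids = split_train_test(
        list(meta.index),
        SplitSpec(config.train_fraction, seed=config.seed,
                  stratify=config.stratify_split),
        strata=list(meta["level"]))
    logger.info("split: %d train / %d test", len(train_ids), len(test_ids))

    selection_rows, model_rows = [], []
    for mi, metal in enumerate(config.metals):
        conc = concentrations.for_metal(metal)
        pot_of = meta["pot_id"]
        y_all = conc.loc[pot_of, "concentration_mgkg"]
        y_all.index = meta.index
        y_scaler = MinMaxScaler()
        if config.scale_before_split:
            y_scaled = pd.Series(
                y_scaler.fit(y_all).transform(y_all), index=y_all.index)
        else:
            y_scaler.fit(y_all.loc[train_ids])
            y_scaled = pd.Series(y_scaler.transform(y_all), index=y_all.index)
        y_train, y_test = y_scaled.loc[train_ids], y_scaled.loc[test_ids]

        for ti, track in enumerate(config.tracks):
            features = feature_tracks[track]
            finite_cols = features.columns[np.isfinite(features).all(axis=0)]
            X_all = features[finite_cols]
            x_scaler = MinMaxScaler()
            if config.scale_before_split:
                X_scaled = x_scaler.fit(X_all).transform(X_all)
            else:
                x_scaler.fit(X_all.loc[train_ids])
                X_scaled = x_scaler.transform(X_all)
            X_train, X_test = X_scaled.loc[train_ids], X_scaled.loc[test_ids]

            sub_seed = (config.seed * 1000 + mi * 10 + ti) % (2 ** 31)
            k = choose_components(X_train, y_train, k_max=config.pls_k_max,
                                  v_folds=config.pls_folds, seed=sub_seed)
            pls_res = PLS1(y_train, X_train).fit(k)
            selection = select_variables(pls_res, use=config.pls_loading)
            logger.info("%s/%s: k=%d, selected %s", metal, track,
                        pls_res.n_components, selection.names)
            selection_rows.append({
                "metal": metal, "track": track,
                "n_components": pls_res.n_components,
                "cum_x_variance_pct": round(pls_res.cumulative_x_variance, 2),
                "cum_y_variance_pct": round(pls_res.cumulative_y_variance, 2),
                "selected_variables": ";".join(selection.names),
                "regions": ";".join(v.region or "-" for v in
                                    selection.variables),
            })

            Xtr = X_train[selection.names]
            Xte = X_test[selection.names]

            mlr = ForwardSelectionMLR(y_train, Xtr).fit(config.mlr_alpha_enter)
            gates = mlr.validity()
            mlr_metrics = evaluate(mlr, Xtr, y_train, Xte, y_test, y_scaler)
            model_rows.append({
                "metal": metal, "track": track, "method": "MLR",
                "structure": mlr.equation(f"C_{metal}"),
                "kernel": "", "n_support": "",
                "dw": round(gates.dw, 3) if np.isfinite(gates.dw) else np.nan,
                "dw_ok": gates.dw_ok,
                "vif_max": (round(max(gates.vifs), 2) if gates.vifs else np.nan),
                "vif_ok": gates.vif_ok,
                "sig_pvalue": gates.regression_pvalue,
                "significance_ok": gates.significance_ok,
                "valid": gates.valid,
                **_metric_cols(mlr_metrics),
            })

            grid = SVRGrid() if config.svr_grid == "full" else FAST_SVR_GRID
            svr = SVRGridSearch(y_train, Xtr, grid).fit(config.svr_folds,
                                                        seed=sub_seed)
            svr_metrics = evaluate(svr, Xtr, y_train, Xte, y_test, y_scaler)
            cfg = svr.config
            model_rows.append({
                "metal": metal, "track": track, "method": "SVR",
                "structure": (f"kernel={cfg['kernel']} C={cfg['C']} "
                              f"eps={cfg['epsilon']} gamma={cfg['gamma']} "
                              f"degree={cfg['degree']} coef0={cfg['coef0']}"),
                "kernel": cfg["kernel"], "n_support": svr.n_support,
                "dw": np.nan, "dw_ok": "", "vif_max": np.nan, "vif_ok": "",
                "sig_pvalue": np.nan, "significance_ok": "", "valid": "",
                **_metric_cols(svr_metrics),
            })

    correlogram = compute_correlogram(pots, concentrations,
                                      metals=config.metals)
    group_means = mean_spectra_by_group(pots, "healthy-vs-stressed")
    return ReportBundle(config, pd.DataFrame(selection_rows),
                        pd.DataFrame(model_rows), correlogram, group_means,
                        pots, concentrations)


def _metric_cols(metrics) -> dict:
    return {
        "r2_train": round(metrics.r2_train, 4),
        "rmse_train_scaled": round(metrics.rmse_train, 4),
        "r2_test": round(metrics.r2_test, 4),
        "rmse_test_scaled": round(metrics.rmse_test, 4),
        "rmse_train_mgkg": round(metrics.rmse_train_original, 4),
        "rmse_test_mgkg": round(metrics.rmse_test_original, 4),
    }
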