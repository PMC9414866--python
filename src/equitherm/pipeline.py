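"""Pipeline orchestration: simulate -> extract -> select -> classify.

The pipeline's central exchange format is the tidy measure table with
one row per (horse, rider, group, session, roi, component, measure):
five bidimensional entropy measures plus the three GLCM entropy
features, extracted from every ROI/component of every thermogram.

Each stage can be run on its own (the ``extract``/``select``/``classify``
CLI subcommands accept externally produced inputs, so real thermograms
can replace the synthetic generator), or :func:`run_full` runs all of
them and writes ``design.csv``, ``measures.csv``, ``ledger.csv``,
``features.csv``, ``accuracy.csv`` and a reproducibility manifest.

One global seed fans out deterministically: the design table uses the
seed itself and the thermogram of design row *i* uses
``SeedSequence([seed, i])``.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import make_thresholds, threshold_sweep
from .entropy2d import ENTROPY_MEASURES, EntropyParams
from .errors import ConfigurationError, EquithermError, UndefinedEntropyError
from .glcm import GLCM_FEATURES, entropy_features, glcm
from .image_prep import ROISpec, decompose_components, extract_roi
from .selection import SelectionLedger, criterion1_select, criterion2_select, criterion3_select
from .synthetic import StudyDesign, TextureModel, default_rois, generate_thermogram, make_design

__all__ = ["PipelineConfig", "extract_measures", "run_selection", "run_classification",
           "run_full", "report", "simulate_images"]

MEASURE_COLS = ["horse", "rider", "group", "session", "roi", "component",
                "measure", "kind", "value", "ratio_pct"]


@dataclass
class PipelineConfig:
    """All tunables of a full synthetic run."""

    seed: int = 0
    n_horses: int = 12
    image_size: tuple[int, int] = (96, 160)
    roi_size: int = 64
    alpha: float = 0.05
    glcm_levels: int = 64
    entropy: EntropyParams = field(default_factory=EntropyParams)
    texture: TextureModel = field(default_factory=TextureModel)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "entropy" in d and isinstance(d["entropy"], dict):
            d["entropy"] = EntropyParams(**d["entropy"])
        if "texture" in d and isinstance(d["texture"], dict):
            d["texture"] = TextureModel(**d["texture"])
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def snapshot(self) -> dict:
        snap = asdict(self)
        # callables cannot be serialized; record the planted amplitudes instead
        amp = self.texture.irregularity_amplitude
        snap["texture"]["irregularity_amplitude"] = {
            f"{s}/{g}": amp(s, g) for s in ("pre", "post") for g in ("L", "M", "H")
        }
        return snap


def simulate_images(config: PipelineConfig):
    """Yield (design_row, SyntheticImage) for every row of the design."""
    design = make_design(StudyDesign(n_horses=config.n_horses, seed=config.seed))
    rois = default_rois(config.image_size, config.roi_size)
    for i, row in design.iterrows():
        ss = np.random.SeedSequence([config.seed, int(i)])
        img = generate_thermogram(
            row, config.texture, size=config.image_size, roi_specs=rois, seed=ss
        )
        yield row, img


def _patch_measures(patch: np.ndarray, params: EntropyParams, glcm_levels: int) -> dict[str, float]:
    out = {}
    for name, fn in ENTROPY_MEASURES.items():
        try:
            out[name] = fn(patch.astype(float), params)[0]
        except UndefinedEntropyError:
            warnings.warn(f"{name} undefined on a patch; recording NaN", RuntimeWarning,
                          stacklevel=2)
            out[name] = float("nan")
    out.update(entropy_features(glcm(patch, levels=glcm_levels)))
    return out


def extract_measures(
    image_iter,
    params: EntropyParams | None = None,
    glcm_levels: int = 64,
) -> pd.DataFrame:
    """Tidy measure table from an iterable of (metadata, rgb, roi_specs).

    ``metadata`` must carry horse/rider/group/session (and ratio_pct when
    available); every ROI is decomposed into gray/red/green/blue and all
    five entropy measures plus the three GLCM entropy features are
    computed per component.
    """
    params = params or EntropyParams()
    rows = []
    for meta, rgb, rois in image_iter:
        meta = dict(meta)
        for roi in rois:
            components = decompose_components(extract_roi(rgb, roi))
            for comp_name, patch in components.items():
                vals = _patch_measures(patch, params, glcm_levels)
                for measure, value in vals.items():
                    rows.append(
                        {
                            "horse": meta["horse"],
                            "rider": meta["rider"],
                            "group": meta["group"],
                            "session": meta["session"],
                            "roi": roi.label,
                            "component": comp_name,
                            "measure": measure,
                            "kind": "glcm" if measure in GLCM_FEATURES else "entropy",
                            "value": value,
                            "ratio_pct": meta.get("ratio_pct", float("nan")),
                        }
                    )
    return pd.DataFrame(rows, columns=MEASURE_COLS)


def _post_series(measures: pd.DataFrame, measure: str, component: str, roi: str):
    """(labels, x, y) of post-exercise observations, ordered by (horse, rider).

    Labels are (horse, rider) pairs so series with missing values (e.g.
    undefined sample entropy) can still be aligned for regression.
    """
    sub = measures[
        (measures.session == "post")
        & (measures.measure == measure)
        & (measures.component == component)
        & (measures.roi == roi)
    ].sort_values(["horse", "rider"])
    labels = list(zip(sub.horse, sub.rider))
    return labels, sub.ratio_pct.to_numpy(), sub.value.to_numpy()


def run_selection(measures: pd.DataFrame, alpha: float = 0.05) -> SelectionLedger:
    """Apply the three selection criteria to a tidy measure table.

    Entropy measures and GLCM features each pass through criteria 1-2;
    the GLCM feature instances surviving both become the baseline set for
    the criterion-3 slope comparison of the entropy survivors.
    """
    entropy_tab = measures[measures.kind == "entropy"]
    glcm_tab = measures[measures.kind == "glcm"]
    if entropy_tab.empty:
        raise ConfigurationError("measure table holds no entropy measures")
    ledger = criterion1_select(entropy_tab, alpha)
    ledger = criterion2_select(entropy_tab, ledger, alpha)

    feature_series = {}
    if not glcm_tab.empty:
        fledger = criterion1_select(glcm_tab, alpha)
        fledger = criterion2_select(glcm_tab, fledger, alpha)
        for _, rec in fledger.selected(2).iterrows():
            key = f"{rec['measure']}/{rec['component']}/{rec['roi']}"
            feature_series[key] = _post_series(
                glcm_tab, rec["measure"], rec["component"], rec["roi"]
            )
        ledger.meta["glcm_ledger"] = fledger.combos

    survivors = ledger.selected(2)
    entropy_series = {
        (rec["measure"], rec["component"], rec["roi"]): _post_series(
            entropy_tab, rec["measure"], rec["component"], rec["roi"]
        )
        for _, rec in survivors.iterrows()
    }
    if len(feature_series) < 2:
        # Not enough baseline features survived their own selection; the
        # slope-similarity criterion cannot be evaluated.
        combos = ledger.combos.copy()
        combos["crit3_n_equal"] = 0
        combos["crit3_pass"] = False
        out = SelectionLedger(combos=combos, features=pd.DataFrame(
            columns=["feature", "slope", "n_low_slope", "n_compared", "retained"]
        ), alpha=alpha, meta=ledger.meta)
        out.meta["crit3_note"] = "fewer than 2 GLCM features passed criteria 1-2"
        return out
    out = criterion3_select(ledger, entropy_series, feature_series, alpha)
    out.meta = {**ledger.meta, **out.meta}
    return out


def run_classification(
    measures: pd.DataFrame, ledger: SelectionLedger, alpha: float = 0.05
) -> pd.DataFrame:
    """Three-threshold light-vs-heavy accuracy for the selected combinations.

    Selected entropy combinations (criterion 3) and the retained GLCM
    feature instances are each scored at mean - SD / mean / mean + SD of
    their pooled light+heavy post-exercise values.
    """
    targets: list[tuple[str, str, str, str]] = [
        (rec["measure"], rec["component"], rec["roi"], "entropy")
        for _, rec in ledger.selected(3).iterrows()
    ]
    if ledger.features is not None and not ledger.features.empty:
        for _, frec in ledger.features[ledger.features.retained].iterrows():
            meas, comp, roi = frec["feature"].split("/")
            targets.append((meas, comp, roi, "glcm"))
    rows = []
    for meas, comp, roi, kind in targets:
        sub = measures[
            (measures.session == "post")
            & (measures.measure == meas)
            & (measures.component == comp)
            & (measures.roi == roi)
        ]
        light = sub[sub.group == "L"].value.to_numpy()
        heavy = sub[sub.group == "H"].value.to_numpy()
        thr = make_thresholds(
            np.concatenate([light, heavy]), description=f"{meas}/{comp}/{roi} pooled L+H post"
        )
        for label, value, summary in zip(thr.labels, thr, threshold_sweep(light, heavy, thr)):
            metrics = summary.metrics(ndigits=2)
            rows.append(
                {
                    "measure": meas, "component": comp, "roi": roi, "kind": kind,
                    "threshold": label, "threshold_value": value,
                    "TP": summary.TP, "FP": summary.FP,
                    "TN": summary.TN, "FN": summary.FN,
                    **metrics,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["measure", "component", "roi", "kind", "threshold", "threshold_value",
                 "TP", "FP", "TN", "FN", "Se", "Sp", "PPV", "NPV"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: PipelineConfig | dict | None = None, out_dir: str | Path | None = None):
    """Run simulate -> extract -> select -> classify on one synthetic study.

    Returns a dict with the design table, measure table, selection
    ledger, accuracy table and manifest; when ``out_dir`` is given the
    CSV outputs and ``manifest.json`` are also written there.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    design_rows = []
    def _iter():
        for row, img in simulate_images(config):
            design_rows.append(row)
            yield row, img.rgb, img.roi_specs
    measures = extract_measures(_iter(), config.entropy, config.glcm_levels)
    design = pd.DataFrame(design_rows).reset_index(drop=True)
    ledger = run_selection(measures, config.alpha)
    accuracy = run_classification(measures, ledger, config.alpha)
    manifest = {
        "package": "equitherm",
        "version": __version__,
        "seed": config.seed,
        "seed_scheme": "design: seed; image row i: SeedSequence([seed, i])",
        "config": config.snapshot(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_images": int(len(design)),
        "n_combinations": int(
            measures[measures.kind == "entropy"]
            .groupby(["measure", "component", "roi"])
            .ngroups
        ),
    }
    outputs = {
        "design": design, "measures": measures, "ledger": ledger,
        "accuracy": accuracy, "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design.to_csv(out / "design.csv", index=False)
        measures.to_csv(out / "measures.csv", index=False)
        ledger.combos.to_csv(out / "ledger.csv", index=False)
        if ledger.features is not None:
            ledger.features.to_csv(out / "features.csv", index=False)
        accuracy.to_csv(out / "accuracy.csv", index=False)
        digests = {
            f.name: _sha256(f)
            for f in sorted(out.glob("*.csv"))
        }
        manifest["digests"] = digests
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outputs


def report(outputs: dict | str | Path) -> str:
    """Human-readable summary: criterion pass-matrices and accuracy grid."""
    if isinstance(outputs, (str, Path)):
        out = Path(outputs)
        if not (out / "ledger.csv").exists():
            raise EquithermError(f"no pipeline outputs found in {out}")
        combos = pd.read_csv(out / "ledger.csv")
        accuracy = pd.read_csv(out / "accuracy.csv") if (out / "accuracy.csv").exists() else pd.DataFrame()
    else:
        combos = outputs["ledger"].combos
        accuracy = outputs["accuracy"]
    lines = []
    for crit in (1, 2, 3):
        col = f"crit{crit}_pass"
        if col not in combos.columns:
            continue
        lines.append(f"Criterion {crit} pass matrix (X = pass):")
        grid = combos.assign(flag=np.where(combos[col].fillna(False), "X", "."))
        for roi, sub in grid.groupby("roi"):
            piv = sub.pivot_table(
                index="measure", columns="component", values="flag", aggfunc="first"
            )
            lines.append(f"  {roi}:")
            lines.append("    " + piv.to_string().replace("\n", "\n    "))
        lines.append("")
    if accuracy.empty:
        lines.append("no combination selected")
    else:
        lines.append("Accuracy of light-vs-heavy detection (rows Se/Sp/PPV/NPV):")
        piv = accuracy.pivot_table(
            index="threshold",
            columns=["measure", "component", "roi"],
            values=["Se", "Sp", "PPV", "NPV"],
        )
        lines.append(piv.round(2).to_string())
    return "\n".join(lines)
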