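"""File formats, run configuration, and report assembly.

Signal dialect: plain text, one amplitude per line, preceded by header
comments ``# ts=...``, ``# t0=...``, ``# label=...``.  Datasets pair one
file per signal with a ``manifest.csv`` (columns: filename, label).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from .classify import ClassificationReport, run_benchmark
from .signal import PASignal
from .synthetic import ClassParameterSpec, SimulationConfig, default_class_table

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_signal",
    "write_signal",
    "read_dataset",
    "write_dataset",
    "write_report",
    "validate_summary",
    "end_to_end",
]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, JSON-serializable."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    i: int = 20
    max_order: int = 10
    order_override: Optional[int] = None
    decimate_to: Optional[float] = 1e8
    fd_band: tuple[float, float] = (1e6, 20e6)
    arma_order: tuple[int, int] = (2, 2)
    split_spec: str = "holdout20"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            classes = sim.pop("classes", None)
            if classes is not None:
                sim["classes"] = [ClassParameterSpec(**c) for c in classes]
            sim = SimulationConfig(**sim)
        d["simulation"] = sim
        if "fd_band" in d:
            d["fd_band"] = tuple(d["fd_band"])
        if "arma_order" in d:
            d["arma_order"] = tuple(d["arma_order"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_signal(signal: PASignal, path: Union[str, Path]) -> None:
    """Write one trace in the headered text dialect (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ts={float(signal.ts):.17g}\n")
        fh.write(f"# t0={float(signal.t0):.17g}\n")
        fh.write(f"# label={signal.label}\n")
        for v in signal.samples:
            if not math.isfinite(v):
                raise ValueError("refusing to write non-finite amplitude")
            fh.write(f"{float(v):.17g}\n")


def read_signal(path: Union[str, Path]) -> PASignal:
    """Parse the headered text dialect back into a :class:`PASignal`."""
    path = Path(path)
    headers: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    headers[key.strip()] = val.strip()
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric line {line!r}") from exc
            if not math.isfinite(v):
                raise ValueError(f"{path}:{lineno}: non-finite amplitude")
            samples.append(v)
    if "ts" not in headers:
        raise ValueError(f"{path}: missing '# ts=' header")
    if not samples:
        raise ValueError(f"{path}: no samples")
    return PASignal(
        samples=np.array(samples),
        ts=float(headers["ts"]),
        t0=float(headers.get("t0", 0.0)),
        label=headers.get("label", "unlabeled"),
    )


def write_dataset(signals: list[PASignal], out_dir: Union[str, Path]) -> Path:
    """One file per signal plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, sig in enumerate(signals):
        fname = f"signal_{k:03d}.txt"
        write_signal(sig, out_dir / fname)
        rows.append({"filename": fname, "label": sig.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest: Union[str, Path]) -> list[PASignal]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    base = manifest.parent
    out = []
    for _, row in df.iterrows():
        sig = read_signal(base / row["filename"])
        sig.label = str(row["label"])
        out.append(sig)
    return out


_SUMMARY_SCHEMA: dict[str, type] = {
    "config_hash": str,
    "seed": int,
    "split_spec": str,
    "accuracy_percent": dict,
}


def validate_summary(summary: dict) -> None:
    """Check the machine-readable summary against the shipped schema."""
    for key, typ in _SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} must be {typ.__name__}")
    for fam, acc in summary["accuracy_percent"].items():
        if not isinstance(acc, (int, float)) or not math.isfinite(acc):
            raise ValueError(f"accuracy for {fam!r} is not a finite number")


def _report_frame(report: ClassificationReport) -> pd.DataFrame:
    return pd.DataFrame(
        report.confusion,
        index=pd.Index(report.class_labels, name="true"),
        columns=report.class_labels,
    )


def write_report(results: dict, out_dir: Union[str, Path], config: RunConfig) -> dict:
    """Write the benchmark outputs: confusion CSVs, LD scores, ellipse specs,
    group-statistics table, per-class NRMSE table, and a JSON summary
    embedding the config hash and seed.  Returns the summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accuracy: dict[str, float] = {}
    for family, res in results.get("families", {}).items():
        report: ClassificationReport = res["report"]
        accuracy[family] = report.accuracy
        _report_frame(report).to_csv(out_dir / f"confusion_{family}.csv")
        scores = res["train_scores"]
        pd.DataFrame(
            {
                "label": res["train_labels"],
                "LD1": scores[:, 0],
                "LD2": scores[:, 1],
            }
        ).to_csv(out_dir / f"ld_scores_{family}.csv", index=False)
        ell_rows = []
        for c, e in res["ellipses"].items():
            ell_rows.append(
                {
                    "label": c,
                    "center_x": e.center[0],
                    "center_y": e.center[1],
                    "semi_axis_1": e.semi_axes[0],
                    "semi_axis_2": e.semi_axes[1],
                    "rotation_rad": e.rotation,
                    "level": e.level,
                }
            )
        if ell_rows:
            pd.DataFrame(ell_rows).to_csv(out_dir / f"ellipses_{family}.csv", index=False)

    comp_rows = []
    for pname, gc in results.get("group_comparisons", {}).items():
        for (a, b), info in gc.pairwise.items():
            comp_rows.append(
                {
                    "parameter": pname,
                    "anova_F": gc.anova_F,
                    "anova_p": gc.anova_p,
                    "class_a": a,
                    "class_b": b,
                    "p_raw": info["p_raw"],
                    "p_adj": info["p_adj"],
                    "stars": info["stars"],
                }
            )
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out_dir / "group_comparisons.csv", index=False)

    nrmse = results.get("nrmse_by_class", {})
    if nrmse:
        pd.DataFrame(
            [{"label": c, "nrmse_percent": v} for c, v in nrmse.items()]
        ).to_csv(out_dir / "nrmse_by_class.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "split_spec": results.get("split_spec", config.split_spec),
        "accuracy_percent": accuracy,
        "nrmse_by_class": nrmse,
    }
    validate_summary(summary)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def end_to_end(config: RunConfig, out_dir: Union[str, Path]) -> int:
    """Simulate, benchmark all four families, and write the report.

    Returns 0 on success; nonzero when more than 20% of per-sample feature
    extractions failed (failures are logged and excluded, never imputed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    sim = config.simulation
    if config.seed is not None:
        from dataclasses import replace

        sim = replace(sim, seed=config.seed)
    results = run_benchmark(
        sim,
        split_spec=config.split_spec,
        fd_band=config.fd_band,
        arma_order=config.arma_order,
        ss_options={
            "i": config.i,
            "max_order": config.max_order,
            "order_override": config.order_override,
            "decimate_to": config.decimate_to,
        },
    )
    write_report(results, out_dir, config)
    n_total = 0
    n_excluded = 0
    for res in results.get("families", {}).values():
        rep = res["report"]
        n_excluded += rep.meta.get("n_excluded_train", 0) + rep.meta.get(
            "n_excluded_test", 0
        )
        n_total += (
            len(res["train_features"])
            + len(res["test_features"])
            + rep.meta.get("n_excluded_train", 0)
            + rep.meta.get("n_excluded_test", 0)
        )
    if n_total and n_excluded / n_total > 0.20:
        logger.error("%d of %d extractions failed (> 20%%)", n_excluded, n_total)
        return 1
    return 0
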