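"""End-to-end orchestration: simulate/load -> DGE -> recovery -> splicing -> report.

A run is driven by one :class:`RunConfig` (plain-YAML serializable). Every
stage writes its table under the output directory; a manifest records the
package version, seed, thresholds and SHA-256 checksums of every written
file, so re-running with the same config reproduces a byte-identical
bundle. The JSON report is validated against the packaged schema file on
every run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .countdata import CountMatrix
from .errors import ConfigError, DataError, StageError
from . import dge as dge_mod
from . import recovery as rec_mod
from . import splicing as spl_mod
from .simulate import SimConfig, SpliceSimConfig, TreatmentArm, generate_counts, generate_splice_events

logger = logging.getLogger("txrescue")

SCHEMA_VERSION = 1
FLOAT_FORMAT = "%.10g"


# ------------------------------------------------------------------- config
@dataclass(frozen=True)
class Thresholds:
    """Every published analysis threshold, as a config default."""

    alpha: float = 0.05
    lfc: float = 1.0
    recovery_bins: tuple[float, float, float] = (10.0, 50.0, 150.0)
    recovery_eps: float = 1.0
    min_dpsi: float = 25.0
    min_reads: int = 10
    splice_alpha: float = 0.05
    min_move: float = 5.0
    min_mean_count: float = 5.0

    def validate(self) -> None:
        positive = {
            "alpha": self.alpha,
            "lfc": self.lfc,
            "recovery_eps": self.recovery_eps,
            "min_dpsi": self.min_dpsi,
            "min_reads": self.min_reads,
            "splice_alpha": self.splice_alpha,
            "min_move": self.min_move,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.min_mean_count < 0:
            raise ConfigError("min_mean_count must be >= 0")
        lo, mid, hi = self.recovery_bins
        if not lo < mid < hi:
            raise ConfigError("recovery_bins must be strictly increasing")


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end run: data source, contrasts, thresholds, seed, outdir."""

    seed: int = 0
    outdir: str = "results/run"
    simulation: SimConfig = field(default_factory=SimConfig)
    splice_simulation: SpliceSimConfig = field(default_factory=SpliceSimConfig)
    #: when set, counts/design are read from these TSVs instead of simulated
    counts_tsv: str | None = None
    design_tsv: str | None = None
    events_tsv: str | None = None
    events_design_tsv: str | None = None
    hard_targets_file: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    # groups; default: taken from the simulation config
    control_group: str | None = None
    disease_group: str | None = None
    treatment_arms: tuple[str, ...] | None = None

    def resolved_groups(self) -> tuple[str, str, tuple[str, ...]]:
        control = self.control_group or self.simulation.control_group
        disease = self.disease_group or self.simulation.disease_group
        arms = (
            self.treatment_arms
            if self.treatment_arms is not None
            else tuple(a.name for a in self.simulation.arms)
        )
        return control, disease, arms

    def validate(self) -> None:
        self.thresholds.validate()
        if self.counts_tsv is None:
            self.simulation.validate()
        if self.events_tsv is None:
            self.splice_simulation.validate()

    # ------------------------------------------------------------- YAML I/O
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "simulation" in data and isinstance(data["simulation"], dict):
            sim = dict(data["simulation"])
            if "arms" in sim:
                sim["arms"] = tuple(
                    TreatmentArm(**a) if isinstance(a, dict) else a for a in sim["arms"]
                )
            for key in ("effect_log2_range", "baseline_mean_log_params"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["simulation"] = SimConfig(**sim)
        if "splice_simulation" in data and isinstance(data["splice_simulation"], dict):
            sp = dict(data["splice_simulation"])
            if "arms" in sp:
                sp["arms"] = tuple(tuple(a) for a in sp["arms"])
            if "control_psi_range" in sp:
                sp["control_psi_range"] = tuple(sp["control_psi_range"])
            data["splice_simulation"] = SpliceSimConfig(**sp)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            th = dict(data["thresholds"])
            if "recovery_bins" in th:
                th["recovery_bins"] = tuple(th["recovery_bins"])
            data["thresholds"] = Thresholds(**th)
        if data.get("treatment_arms") is not None:
            data["treatment_arms"] = tuple(data["treatment_arms"])
        return cls(**data)

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def read_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls.from_dict(data or {})
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML/JSON round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ------------------------------------------------------------------ running
def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig, quiet: bool = False) -> dict:
    """Execute every stage in order; return the report dict.

    Any stage failure raises :class:`StageError` naming the stage. Outputs
    are deterministic under a fixed config (including the seed).
    """
    level = logging.WARNING if quiet else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    control, disease, arms = config.resolved_groups()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    # ------------------------------------------------------------- stage: data
    stage = "data"
    try:
        if config.counts_tsv is not None:
            if config.design_tsv is None:
                raise ConfigError("counts_tsv given without design_tsv")
            matrix = CountMatrix.read(config.counts_tsv, config.design_tsv)
            truth = None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            matrix, truth = generate_counts(sim)
        for group in [control, disease, *arms]:
            if group not in matrix.groups:
                raise ConfigError(
                    f"contrast group {group!r} is missing from the design "
                    f"(available: {matrix.groups})"
                )
        matrix.write(out / "counts.tsv", out / "design.tsv")
        if truth is not None:
            _write_tsv(truth, out / "truth.tsv")
        logger.info("data: %d genes x %d samples", *matrix.counts.shape)
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, str(exc)) from exc

    # ---------------------------------------------------- stage: normalization
    stage = "normalize"
    try:
        sf, norm = dge_mod.normalize_counts(matrix)
        sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t", float_format=FLOAT_FORMAT)
        _write_tsv(norm, out / "normalized_counts.tsv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -------------------------------------------------------------- stage: dge
    stage = "dge"
    try:
        contrasts: dict[str, pd.DataFrame] = {}
        name = f"{control}_vs_{disease}"
        contrasts[name] = dge_mod.test_differential(
            matrix, control, disease,
            alpha=th.alpha, lfc_threshold=th.lfc, min_mean_count=th.min_mean_count,
        )
        for arm in arms:
            cname = f"{disease}_vs_{arm}"
            contrasts[cname] = dge_mod.test_differential(
                matrix, disease, arm,
                alpha=th.alpha, lfc_threshold=th.lfc, min_mean_count=th.min_mean_count,
            )
        for cname, table in contrasts.items():
            _write_tsv(table, out / f"dge_{cname}.tsv")
        disease_set = rec_mod.disease_related_genes(
            contrasts[f"{control}_vs_{disease}"], alpha=th.alpha, lfc_threshold=th.lfc
        )
        logger.info("dge: %d disease-related genes", len(disease_set))
    except (ConfigError, DataError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --------------------------------------------------------- stage: recovery
    stage = "recovery"
    try:
        dge_section: dict = {"n_disease_related": int(len(disease_set)), "arms": {}}
        recovery_tables: dict[str, pd.DataFrame] = {}
        for arm in arms:
            table = rec_mod.recovery_table(
                norm, matrix.design, control, disease, arm,
                disease_genes=disease_set.index,
                eps=th.recovery_eps, bins=th.recovery_bins,
            )
            recovery_tables[arm] = table
            _write_tsv(table, out / f"recovery_{arm}.tsv")
            flags, rev_summary = rec_mod.reversal_calls(
                disease_set, contrasts[f"{disease}_vs_{arm}"],
                alpha=th.alpha, lfc_threshold=th.lfc,
            )
            _write_tsv(flags, out / f"reversals_{arm}.tsv")
            # improvements additionally require at least partial magnitude recovery
            improved = flags.index[flags["reversal"]].intersection(
                table.index[table["pct_recovery"] >= th.recovery_bins[0]]
            )
            n_alt = rev_summary["n_treatment_altered"]
            dge_section["arms"][arm] = {
                "n_altered_vs_disease": n_alt,
                "n_reversals": rev_summary["n_reversals"],
                "reversal_fraction_pct": rev_summary["reversal_fraction_pct"],
                "n_improvements": int(len(improved)),
                "improvement_fraction_pct": (
                    100.0 * len(improved) / n_alt if n_alt else float("nan")
                ),
                "n_missing_from_contrast": len(rev_summary["missing_genes"]),
                "intersection_ratio_with_disease_set": rec_mod.intersection_ratio(
                    disease_set.index,
                    dge_mod.call_altered(
                        contrasts[f"{disease}_vs_{arm}"], th.alpha, th.lfc
                    ),
                )
                if len(disease_set)
                else 0.0,
            }
        recovery_section = (
            rec_mod.recovery_summary(recovery_tables) if recovery_tables else {"arms": {}, "pairs": {}}
        )
    except (ConfigError, DataError) as exc:
        raise StageError(stage, str(exc)) from exc

    # ----------------------------------------------------- stage: hard targets
    stage = "hard_targets"
    try:
        targets: list[str] | None = None
        if config.hard_targets_file is not None:
            targets = rec_mod.read_target_list(config.hard_targets_file)
        elif truth is not None and truth["is_hard_target"].any():
            targets = list(truth.index[truth["is_hard_target"]])
        hard_section = None
        if targets:
            arm_contrasts = {f"{disease}_vs_{arm}": contrasts[f"{disease}_vs_{arm}"] for arm in arms}
            if arm_contrasts:
                report = rec_mod.hard_target_report(
                    arm_contrasts, targets, alpha=th.alpha, lfc_threshold=th.lfc
                )
                _write_tsv(report["matrix"], out / "hard_target_matrix.tsv")
                hard_section = {
                    "n_targets": report["n_targets"],
                    "n_present": report["n_present"],
                    "n_missing": len(report["missing"]),
                    "altered_counts": report["altered_counts"],
                }
    except (ConfigError, DataError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --------------------------------------------------------- stage: splicing
    stage = "splicing"
    try:
        if config.events_tsv is not None:
            events = pd.read_csv(config.events_tsv, sep="\t")
            ev_design = (
                pd.read_csv(config.events_design_tsv, sep="\t", index_col=0)["group"]
                if config.events_design_tsv
                else matrix.design
            )
            sp_truth = None
        else:
            sp_cfg = dataclasses.replace(
                config.splice_simulation,
                seed=config.seed + 1,
                control_group=control,
                disease_group=disease,
                arms=tuple(
                    (arm, _arm_recovery(config.simulation, arm)) for arm in arms
                ),
            )
            events, ev_design, sp_truth = generate_splice_events(sp_cfg)
        events.to_csv(out / "events.tsv", sep="\t", index=False)
        ev_design.to_frame("group").to_csv(out / "events_design.tsv", sep="\t")
        if sp_truth is not None:
            _write_tsv(sp_truth, out / "splice_truth.tsv")
        event_table = spl_mod.summarize_events(
            events, ev_design, control, disease, arms,
            min_dpsi=th.min_dpsi, min_reads=th.min_reads,
            alpha=th.splice_alpha, min_move=th.min_move,
        )
        _write_tsv(event_table, out / "splice_events.tsv")
        n_pass = int(event_table["passes_filter"].sum())
        splicing_section = {
            "n_events": int(len(event_table)),
            "n_pass_filter": n_pass,
            "arms": {},
        }
        for arm in arms:
            rev = event_table[f"reversed_{arm}"]
            psr = event_table.loc[rev.fillna(False).to_numpy(bool), f"psr_{arm}"]
            splicing_section["arms"][arm] = {
                "n_reversed": int(rev.fillna(False).sum()),
                "mean_psr_pct": float(psr.mean()) if len(psr) else float("nan"),
            }
        logger.info("splicing: %d of %d events pass the filter", n_pass, len(event_table))
    except (ConfigError, DataError) as exc:
        raise StageError(stage, str(exc)) from exc

    # ----------------------------------------------------------- stage: report
    stage = "report"
    try:
        report = write_report(
            out,
            seed=config.seed,
            thresholds=th,
            control=control,
            disease=disease,
            arms=arms,
            dge_section=dge_section,
            recovery_section=recovery_section,
            hard_section=hard_section,
            splicing_section=splicing_section,
        )
        _write_manifest(out, config)
    except (ConfigError, DataError) as exc:
        raise StageError(stage, str(exc)) from exc
    return report


def _arm_recovery(sim: SimConfig, arm_name: str) -> float:
    for arm in sim.arms:
        if arm.name == arm_name:
            return arm.recovery_fraction
    return 0.8


# ------------------------------------------------------------------- report
def load_schema() -> dict:
    with resources.files("txrescue").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _check_schema(report: dict, schema: dict, path: str = "") -> None:
    type_map = {"int": int, "float": (int, float), "str": str, "list": list, "dict": dict}
    for key, expected in schema.items():
        optional = isinstance(expected, str) and expected.endswith("?")
        if key not in report:
            raise DataError(f"report missing required key {path + key!r}")
        value = report[key]
        if value is None:
            if optional or report.get("status") == "incomplete":
                continue
            raise DataError(f"report key {path + key!r} is null in a complete report")
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise DataError(f"report key {path + key!r} must be an object")
            _check_schema(value, expected, path + key + ".")
        else:
            expected_name = expected.rstrip("?")
            if not isinstance(value, type_map[expected_name]):
                raise DataError(
                    f"report key {path + key!r} has type {type(value).__name__}, "
                    f"expected {expected_name}"
                )


def write_report(
    outdir: str | Path,
    seed: int,
    thresholds: Thresholds,
    control: str,
    disease: str,
    arms: tuple[str, ...],
    dge_section: dict | None,
    recovery_section: dict | None,
    hard_section: dict | None,
    splicing_section: dict | None,
) -> dict:
    """Assemble, schema-validate and write report.json; returns the report.

    Missing sections mark the report "incomplete" (hard targets are
    optional: a run without a target list is still complete).
    """
    status = "complete" if (dge_section is not None and recovery_section is not None
                            and splicing_section is not None) else "incomplete"
    report = {
        "schema_version": SCHEMA_VERSION,
        "status": status,
        "seed": int(seed),
        "control_group": control,
        "disease_group": disease,
        "treatment_arms": list(arms),
        "thresholds": _plain(dataclasses.asdict(thresholds)),
        "dge": _plain(dge_section) if dge_section is not None else None,
        "recovery": _plain(recovery_section) if recovery_section is not None else None,
        "hard_targets": _plain(hard_section) if hard_section is not None else None,
        "splicing": _plain(splicing_section) if splicing_section is not None else None,
    }
    _check_schema(report, load_schema())
    path = Path(outdir) / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "txrescue",
        "version": __version__,
        "seed": int(config.seed),
        "thresholds": _plain(dataclasses.asdict(config.thresholds)),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
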