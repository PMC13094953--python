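"""End-to-end orchestration: simulate -> qc -> pair -> agree -> concord.

A single :class:`PipelineConfig` drives the whole analysis; the report
bundle embeds the resolved configuration (including the Clarke zone
geometry actually used) so every number in it is reproducible.  All
randomness flows from the config seed, so re-running a pipeline yields a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import RepeatedBlandAltman
from .clarke import ZoneConfig, classify_clarke, default_zone_configs
from .concordance import ConcordanceAnalysis
from .core import (
    ANALYSIS_PARAMETERS,
    AbnormalityThreshold,
    AgreementConfig,
    DEFAULT_THRESHOLDS,
    PairingConfig,
    QCRuleConfig,
)
from .io import (
    qc_config_to_dict,
    read_device_table,
    read_episode_table,
    read_nurse_table,
    thresholds_to_list,
    write_episode_table,
    write_table,
)
from .pairing import match_pairs, pair_counts
from .qc import apply_qc, completeness
from .synth import SynthConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``synth`` (generate a cohort) or the three input paths must be
    set.  ``out_dir`` receives intermediate tables, the JSON report and
    its markdown rendering.
    """

    out_dir: str | Path = "wardmon_out"
    synth: SynthConfig | None = None
    device_path: str | Path | None = None
    nurse_path: str | Path | None = None
    episodes_path: str | Path | None = None
    nurse_temp_adjusted: bool | None = None
    qc: QCRuleConfig = field(default_factory=QCRuleConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)
    zone_configs: dict[str, ZoneConfig] | None = None
    thresholds: tuple[AbnormalityThreshold, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.synth is None and not (
            self.device_path and self.nurse_path and self.episodes_path
        ):
            raise ValueError(
                "either a synth config or device/nurse/episodes paths are required"
            )


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the consolidated report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- inputs ------------------------------------------------------------
    if config.synth is not None:
        device, nurse, episodes, truth = _stage("simulate")(generate_cohort)(
            config.synth
        )
        write_table(device, out / "device.csv")
        write_table(nurse, out / "nurse.csv")
        write_episode_table(episodes, out / "episodes.csv")
        truth_summary = {
            "n_injected_artifacts": int(len(truth.artifact_locations)),
            "n_episode_windows": int(len(truth.episode_windows)),
        }
    else:
        device = _stage("read")(read_device_table)(config.device_path)
        nurse = _stage("read")(read_nurse_table)(
            config.nurse_path, temp_adjusted=config.nurse_temp_adjusted
        )
        episodes = _stage("read")(read_episode_table)(config.episodes_path)
        truth_summary = None

    # -- qc ----------------------------------------------------------------
    clean, flags, rates = _stage("qc")(apply_qc)(device, config.qc)
    report_completeness = _stage("qc")(completeness)(device, episodes)
    write_table(clean, out / "device_clean.csv")
    write_table(flags, out / "flags.csv")

    # -- pairing -----------------------------------------------------------
    pairs, exclusions = _stage("pair")(match_pairs)(nurse, clean, config.pairing)
    write_table(pairs, out / "pairs.csv")
    write_table(exclusions, out / "pair_exclusions.csv")

    # -- agreement ---------------------------------------------------------
    zone_configs = config.zone_configs or default_zone_configs()
    agreement_summaries = []
    zone_summaries = []
    for param in ANALYSIS_PARAMETERS:
        col = param.value
        sub = pairs.loc[pairs["parameter"] == col]
        if sub["patient_id"].nunique() >= 2:
            res = _stage("agree")(
                RepeatedBlandAltman.from_pairs(pairs, col, config.agreement).fit
            )()
            agreement_summaries.append(res.to_dict())
        if col in zone_configs and len(sub):
            _, zsum = _stage("agree")(classify_clarke)(pairs, zone_configs[col])
            zone_summaries.append(zsum.to_dict())

    # -- concordance -------------------------------------------------------
    conc = _stage("concord")(
        ConcordanceAnalysis(clean, nurse, config.thresholds).fit
    )()

    report = {
        "software": {"package": "wardmon", "version": __version__},
        "config": {
            "qc": qc_config_to_dict(config.qc),
            "pairing": {
                "window_minutes": config.pairing.window_minutes,
                "selection": config.pairing.selection,
            },
            "agreement": {"loa_multiplier": config.agreement.loa_multiplier},
            "thresholds": thresholds_to_list(list(config.thresholds)),
            "zones": {k: v.to_dict() for k, v in zone_configs.items()},
            "synth_seed": config.synth.seed if config.synth else None,
            "synth_n_patients": config.synth.n_patients if config.synth else None,
        },
        "completeness": report_completeness.to_dict(),
        "artifacts": {
            "total_flags": int(len(flags)),
            "per_parameter_rule": rates.to_dict(orient="records"),
        },
        "pair_counts": pair_counts(pairs),
        "agreement": agreement_summaries,
        "clarke": zone_summaries,
        "concordance": conc.to_dict(),
    }
    if truth_summary is not None:
        report["ground_truth"] = truth_summary

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    (out / "report.md").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable markdown rendering of a report bundle."""
    if not report.get("concordance", {}).get("thresholds"):
        raise ValueError("report bundle is incomplete: no concordance section")
    lines: list[str] = []
    add = lines.append
    add("# Ward-monitoring agreement report")
    add("")
    sw = report["software"]
    add(f"Produced by {sw['package']} {sw['version']}.")
    add("")

    c = report["completeness"]
    add("## Data completeness")
    add("")
    add(
        f"Of {c['expected_slots']} expected 5-minute measurement slots, "
        f"{c['missing_slots']} ({c['missing_pct']}%) were missing; "
        f"{c['complete_records']} obtained records were complete for all "
        "five parameters."
    )
    add("")
    add("| parameter | absent among obtained | % |")
    add("|---|---|---|")
    for k, v in c["parameter_absent"].items():
        add(f"| {k} | {v} | {c['parameter_absent_pct'][k]} |")
    add("")

    add("## Artifacts")
    add("")
    add(f"Total flags: {report['artifacts']['total_flags']}")
    add("")
    add("| parameter | rule | flags | obtained | rate % |")
    add("|---|---|---|---|---|")
    for row in report["artifacts"]["per_parameter_rule"]:
        add(
            f"| {row['parameter']} | {row['rule']} | {row['n_flags']} | "
            f"{row['n_obtained']} | {100 * row['rate']:.2f} |"
        )
    add("")

    add("## Matched pairs")
    add("")
    add("| parameter | pairs |")
    add("|---|---|")
    for k, v in report["pair_counts"].items():
        add(f"| {k} | {v} |")
    add("")

    add("## Bland-Altman (device - nurse)")
    add("")
    add("| parameter | n | subjects | bias | total SD | LoA |")
    add("|---|---|---|---|---|---|")
    for s in report["agreement"]:
        add(
            f"| {s['parameter']} | {s['n_pairs']} | {s['n_subjects']} | "
            f"{s['bias']:.2f} | {s['total_sd']:.2f} | "
            f"[{s['loa_lower']:.2f}, {s['loa_upper']:.2f}] |"
        )
    add("")

    add("## Clarke Error Grid")
    add("")
    add("| parameter | n | A % | B % | C % | D % | E % |")
    add("|---|---|---|---|---|---|---|")
    for z in report["clarke"]:
        pct = z["pct"]
        add(
            f"| {z['parameter']} | {z['n']} | "
            + " | ".join(str(pct.get(lab, 0.0)) for lab in "ABCDE")
            + " |"
        )
    add("")

    add("## Abnormality concordance")
    add("")
    add(
        "| threshold | n | agreement (%) | nurse-only (%) | device-only (%) "
        "| kappa [95% CI] | McNemar p | method |"
    )
    add("|---|---|---|---|---|---|---|---|")
    for r in report["concordance"]["thresholds"]:
        ci = r["kappa_ci"]
        add(
            f"| {r['threshold']} | {r['n']} | "
            f"{r['agreement']} ({r['agreement_pct']}) | "
            f"{r['nurse_only']} ({r['nurse_only_pct']}) | "
            f"{r['device_only']} ({r['device_only_pct']}) | "
            f"{r['kappa']:.2f} [{ci[0]:.2f}; {ci[1]:.2f}] | "
            f"{r['mcnemar_p']} | {r['mcnemar_method']} |"
        )
    add("")
    return "\n".join(lines)
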