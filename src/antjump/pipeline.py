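"""End-to-end orchestration: one call chaining every analysis stage.

``run_full_analysis`` produces the derived tables of the study — normalized
muscle metrics, architecture summaries, pairwise fold changes, the
volume-space PCA, leg ratios and jump-energetics feasibility — from either
user-supplied CSVs or the synthetic study cast, and writes them with a
provenance block so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import summarize_architecture
from .compare import leg_ratios, pair_comparisons, pc1_separation, run_pca
from .energetics import energetics_pipeline
from .kinematics import TakeoffMetrics, average_trials, takeoff_metrics
from .reference_data import JUMP_OBSERVATIONS, LEG_OBSERVATIONS
from .scaling import NormalizationMode, normalize_pcsa_by_thorax_surface, relative_fiber_length, relative_pcsa, relative_volume
from .simulate import (
    FiberGenConfig,
    generate_fiber_set,
    generate_jump_trajectory,
    generate_study_cast,
)
from .types import PhysiologicalConstants, SpeciesRecord

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: Path
    seed: int = 0
    constants: PhysiologicalConstants = field(default_factory=PhysiologicalConstants)
    normalization_mode: NormalizationMode = NormalizationMode.MUSCLE_VOLUME
    n_pairs: int = 4
    noise_cv: float = 0.1


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage on the synthetic cast plus the published observations.

    Emits one CSV per derived table under ``config.out_dir`` along with a
    human-readable summary and a JSON provenance block (version, seed,
    constants). Returns the mapping of table name -> written path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    constants = config.constants
    written: dict[str, Path] = {}

    # --- synthetic cast: volumes, normalization, fold changes, PCA -------
    table, species = generate_study_cast(
        seed=config.seed, n_pairs=config.n_pairs, noise_cv=config.noise_cv
    )
    by_name = {s.species_name: s for s in species}

    norm_rows = []
    for sp_name, row in table.iterrows():
        thorax = row["thorax_volume"]
        for code, volume in row.drop("thorax_volume").items():
            norm_rows.append(
                {
                    "species": sp_name,
                    "muscle_code": code,
                    "relative_volume": relative_volume(volume, thorax),
                    "normalization_mode": config.normalization_mode.value,
                }
            )
    written["normalized_metrics"] = _write(
        pd.DataFrame(norm_rows), out / "normalized_metrics.csv"
    )

    norm_df = pd.DataFrame(norm_rows)
    fold_rows = []
    for p in range(config.n_pairs):
        jumper, nonjumper = f"jumper_{p}", f"nonjumper_{p}"
        jm = dict(
            norm_df[norm_df.species == jumper][["muscle_code", "relative_volume"]].values
        )
        nm = dict(
            norm_df[norm_df.species == nonjumper][
                ["muscle_code", "relative_volume"]
            ].values
        )
        fold_rows.extend(
            dataclasses.asdict(c) for c in pair_comparisons(jm, nm, jumper, nonjumper)
        )
    written["pair_comparisons"] = _write(
        pd.DataFrame(fold_rows), out / "pair_comparisons.csv"
    )

    pca = run_pca(table)
    separated, margin = pc1_separation(
        pca, {s.species_name: s.jumping for s in species}
    )
    written["pca_scores"] = _write(
        pca.scores_frame(), out / "pca_scores.csv", index=True
    )
    written["pca_loadings"] = _write(
        pca.loadings_frame(), out / "pca_loadings.csv", index=True
    )
    written["pca_variance"] = _write(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
                "variance_fraction": pca.variance_explained,
            }
        ),
        out / "pca_variance.csv",
    )

    # --- synthetic fiber sets -> architecture summaries ------------------
    arch_rows = []
    for i, sp in enumerate(s for s in species if s.jumping):
        cfg = FiberGenConfig(
            n_fibers=90,
            mean_pennation_deg=9.0,
            sd_pennation_deg=4.0,
            target_volume_m3=float(table.loc[sp.species_name, "IIscm6"]),
            seed=config.seed + 1000 + i,
        )
        fibers = generate_fiber_set(cfg, species_name=sp.species_name)
        summary = summarize_architecture(cfg.target_volume_m3, fibers)
        row = dataclasses.asdict(summary)
        row["relative_pcsa"] = relative_pcsa(
            summary.pcsa_m2, cfg.target_volume_m3, constants
        )
        row["relative_fiber_length"] = relative_fiber_length(
            summary.mean_fiber_length_m, cfg.target_volume_m3, constants
        )
        if config.normalization_mode is NormalizationMode.THORAX_SURFACE:
            row["normalized_effective_pcsa"] = normalize_pcsa_by_thorax_surface(
                summary.effective_pcsa_m2, sp.thorax_volume_m3
            )
        arch_rows.append(row)
    written["architecture"] = _write(
        pd.DataFrame(arch_rows), out / "architecture_summary.csv"
    )

    # --- synthetic kinematics trials -------------------------------------
    trials = []
    for k in range(3):
        trial = generate_jump_trajectory(
            acceleration_m_s2=21.43,
            takeoff_duration_s=0.0199,
            noise_sd_m=1e-5,
            seed=config.seed + 2000 + k,
        )
        trials.append(takeoff_metrics(trial, smoothing_window=21))
    summary = average_trials(trials)
    kin_df = pd.DataFrame(
        [dataclasses.asdict(m) for m in trials]
        + [dataclasses.asdict(summary.mean), dataclasses.asdict(summary.sem)]
    )
    kin_df.insert(0, "row", [f"trial_{k}" for k in range(len(trials))] + ["mean", "sem"])
    written["kinematics"] = _write(kin_df, out / "kinematics_trials.csv")

    # --- leg ratios and energetics from the published observations -------
    leg_rows = []
    for name, obs in LEG_OBSERVATIONS.items():
        r = leg_ratios(
            obs["front_mm"], obs["middle_mm"], obs["hind_mm"],
            obs["body_length_mm"], species_name=name,
        )
        row = dataclasses.asdict(r)
        row["ratio_string"] = r.ratio_string
        row["jumping"] = obs["jumping"]
        leg_rows.append(row)
    written["leg_ratios"] = _write(pd.DataFrame(leg_rows), out / "leg_ratios.csv")

    energetics_rows = []
    for name, obs in JUMP_OBSERVATIONS.items():
        sp = SpeciesRecord(
            species_name=name,
            jumping=True,
            body_length_mm=LEG_OBSERVATIONS[name]["body_length_mm"],
            body_mass_kg=obs["body_mass_kg"],
        )
        kin = TakeoffMetrics(
            duration_s=obs["takeoff_time_s"],
            mean_velocity_m_s=obs["takeoff_speed_m_s"],
            takeoff_velocity_m_s=obs["takeoff_speed_m_s"],
            mean_acceleration_m_s2=obs["takeoff_speed_m_s"] / obs["takeoff_time_s"],
        )
        res = energetics_pipeline(
            sp, kin, measured_volume_m3=obs["measured_muscle_volume_m3"],
            constants=constants,
        )
        row = dataclasses.asdict(res)
        row.pop("constants")
        row["classification"] = res.classification.value
        energetics_rows.append(row)
    written["energetics"] = _write(
        pd.DataFrame(energetics_rows), out / "energetics.csv"
    )

    provenance = {
        "antjump_version": __version__,
        "seed": config.seed,
        "n_pairs": config.n_pairs,
        "noise_cv": config.noise_cv,
        "normalization_mode": config.normalization_mode.value,
        "constants": dataclasses.asdict(constants),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    written["provenance"] = prov_path

    summary_lines = [
        f"antjump {__version__} full analysis (seed {config.seed})",
        f"synthetic cast: {config.n_pairs} jumper/non-jumper pairs, cv {config.noise_cv}",
        f"PCA PC1 variance fraction: {pca.variance_explained[0]:.4f}",
        f"PC1 separates jumpers from non-jumpers: {separated} (margin {margin:.3f})",
        "energetics classifications: "
        + ", ".join(f"{r['species_name']}: {r['classification']}" for r in energetics_rows),
    ]
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    written["summary"] = summary_path
    logger.info("full analysis written to %s", out)
    return written


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
    return path
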