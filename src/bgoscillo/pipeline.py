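"""End-to-end orchestration of the synthetic-session analyses.

``run_pipeline`` generates a normal task session and a parkinsonian
oscillatory session, then chains every analysis stage — validation, PSTH and
responsive-bin statistics, increase/decrease balance, input-downstream
similarity, envelope and LFP spectra with artifact removal, spike-field
coherence/phase/STA with dilution control, and discharge-rate summaries —
writing CSV/JSON outputs, a handful of summary figures regenerated from
those files, and a manifest with the config hash and per-file checksums so
reruns are verifiable: deterministic stages reproduce bit-identical data
files under the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import balance, dataio, firing_rate, pairsim, psth, spectral, sync, synthgen
from .types import ValidationError


@dataclass
class PipelineConfig:
    """Single-file configuration of the demo pipeline.

    ``periods`` uses seconds after cue onset: cue [0, 2), delay [2, 8).
    """

    seed: int = 0
    out_dir: str = "bgoscillo_out"
    n_trials_per_type: int = 15
    n_task_units_per_structure: int = 4
    n_osc_units_per_structure: int = 2
    osc_span_s: float = 180.0
    osc_depth: float = 0.8
    osc_freq_hz: float = 10.0
    include_mua: bool = True
    band_hz: tuple = (8.0, 15.0)
    tail_hz: tuple = (55.0, 75.0)
    periods: dict = field(
        default_factory=lambda: {"cue": (0.0, 2.0), "delay": (2.0, 8.0)}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        if "tail_hz" in raw:
            raw["tail_hz"] = tuple(raw["tail_hz"])
        if "periods" in raw:
            raw["periods"] = {k: tuple(v) for k, v in raw["periods"].items()}
        return cls(**raw)


#: Task-modulation templates: downstream and STN units step up during the
#: cue and down during the delay; MSNs carry a small cue increase; TANs a
#: brief outcome response. Effect sizes are free parameters of the generator.
def default_task_profiles() -> dict:
    b = synthgen.DEFAULT_BASELINES_HZ
    return {
        "MSN": synthgen.RateProfile(b["MSN"], [("cue", 1, 4.0)]),
        "TAN": synthgen.RateProfile(b["TAN"], [("cue", -1, 3.0), ("outcome", 1, 6.0)]),
        "STN": synthgen.RateProfile(b["STN"], [("cue", 1, 15.0), ("delay", -1, 10.0)]),
        "GPe": synthgen.RateProfile(b["GPe"], [("cue", 1, 20.0), ("delay", -1, 15.0)]),
        "GPi": synthgen.RateProfile(b["GPi"], [("cue", 1, 20.0), ("delay", -1, 15.0)]),
        "SNr": synthgen.RateProfile(b["SNr"], [("cue", 1, 20.0), ("delay", -1, 15.0)]),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    Raises ``ValidationError`` naming the stage and record on failure.
    """
    out = Path(config.out_dir)
    data_dir = out / "data"
    res_dir = out / "results"
    fig_dir = out / "figures"
    for d in (data_dir, res_dir, fig_dir):
        d.mkdir(parents=True, exist_ok=True)

    # --- stage: synth -----------------------------------------------------
    normal_cfg = synthgen.SessionConfig(
        n_trials_per_type=config.n_trials_per_type,
        state="normal",
        seed=config.seed,
    )
    trials, task_units = synthgen.gen_task_session(
        normal_cfg, default_task_profiles(), config.n_task_units_per_structure
    )
    dataio.write_trials(trials, data_dir / "normal" / "trials.csv")
    dataio.write_spike_trains(task_units, data_dir / "normal")

    park_cfg = synthgen.SessionConfig(
        state="parkinsonian",
        seed=config.seed + 1,
        osc_depth=config.osc_depth,
        osc_freq_hz=config.osc_freq_hz,
    )
    osc_units, osc_lfps, osc_muas = [], {}, {}
    for structure in ("MSN", "TAN", "STN", "GPe", "SNr"):
        for k in range(config.n_osc_units_per_structure):
            uid = f"{structure}_park_{k:03d}"
            train, lfp, mua = synthgen.gen_oscillatory_pair(
                park_cfg,
                structure=structure,
                span_s=config.osc_span_s,
                unit_id=uid,
                include_mua=config.include_mua,
            )
            osc_units.append(train)
            osc_lfps[uid] = lfp
            if mua is not None:
                osc_muas[uid] = mua
            dataio.write_signal(lfp, data_dir / "parkinsonian" / f"{uid}.lfp")
    dataio.write_spike_trains(osc_units, data_dir / "parkinsonian")

    # --- stage: validate --------------------------------------------------
    summary = dataio.validate_directory(data_dir)
    if summary["errors"]:
        raise ValidationError(f"stage validate: {summary['errors'][0]}")
    _write_json(res_dir / "validation.json", summary)

    # --- stage: psth + balance -------------------------------------------
    keys = [(t, "delayed") for t in ("appetitive", "neutral", "aversive")]
    profiles = psth.build_profiles(task_units, trials, keys)
    _, frac, frac_periods = psth.fraction_responsive(profiles, config.periods)
    downstream_profiles = [
        p for p in profiles if p.structure in pairsim.DOWNSTREAM_STRUCTURES
    ]
    bal_df, bal_periods = balance.balance_series(downstream_profiles, config.periods)
    bal_df.to_csv(res_dir / "balance.csv", index=False)
    _write_json(
        res_dir / "psth_summary.json",
        {
            "n_profiles": len(profiles),
            "fraction_responsive_period_means": frac_periods,
            "balance_period_means": bal_periods,
        },
    )

    # --- stage: pairsim ---------------------------------------------------
    input_profiles = [p for p in profiles if p.structure in pairsim.INPUT_STRUCTURES]
    pairs = pairsim.pair_analysis(
        input_profiles, downstream_profiles, config.periods["cue"]
    )
    pairs.to_csv(res_dir / "pairs.csv", index=False)

    # --- stage: spectra ---------------------------------------------------
    spectra_summary = {}
    for uid, mua in osc_muas.items():
        env = spectral.preprocess_mua(mua)
        spec = spectral.welch_psd(env)
        peak = spectral.psd_peak_zscore(spec, config.band_hz, config.tail_hz)
        spectra_summary[uid] = {"peak_hz": peak.peak_hz, "z": peak.z}
    lfp_spectra_summary = {}
    for uid, lfp in osc_lfps.items():
        spec = spectral.remove_psd_artifacts(spectral.lfp_psd(lfp))
        peak = spectral.psd_peak_zscore(spec, config.band_hz, config.tail_hz)
        lfp_spectra_summary[uid] = {"peak_hz": peak.peak_hz, "z": peak.z}
    _write_json(
        res_dir / "spectra_summary.json",
        {"mua_envelope": spectra_summary, "lfp": lfp_spectra_summary},
    )

    # --- stage: sync ------------------------------------------------------
    sync_summary = {}
    lfp_zs, coh_peaks = [], []
    for train in osc_units:
        lfp = osc_lfps[train.unit_id]
        sig = sync.spike_rate_signal(train, lfp.fs_hz, span_s=train.span_s)
        coh = sync.ms_coherence(sig, lfp, band=config.band_hz)
        sync_summary[train.unit_id] = {
            "peak_hz": coh.peak_hz,
            "peak_coh": coh.peak_coh,
            "phase_deg": coh.phase_at_peak_deg,
        }
        lfp_zs.append(lfp_spectra_summary[train.unit_id]["z"])
        coh_peaks.append(coh.peak_coh)
    entrained_phases = [
        sync_summary[t.unit_id]["phase_deg"]
        for t in osc_units
        if synthgen.DEFAULT_ENTRAINMENT.get(t.structure, False)
    ]
    hist = sync.phase_histogram(entrained_phases)
    slope, intercept, r, p = sync.peak_vs_coherence_regression(lfp_zs, coh_peaks)

    msn_rates = [t.rate_hz for t in osc_units if t.structure == "MSN"]
    target = float(np.mean(msn_rates)) if msn_rates else 2.0
    sta_summary = {}
    for train in osc_units:
        lfp = osc_lfps[train.unit_id]
        sta = sync.sta_lfp(train, lfp)
        diluted = sync.dilute_spike_train(train, target, seed=config.seed)
        sta_d = sync.sta_lfp(diluted, lfp)
        sta_summary[train.unit_id] = {
            "n_spikes": sta.n_spikes,
            "n_spikes_diluted": sta_d.n_spikes,
            "sta_correlation": float(np.corrcoef(sta.sta, sta_d.sta)[0, 1]),
        }
    _write_json(
        res_dir / "sync_summary.json",
        {
            "per_unit": sync_summary,
            "phase_mean_deg": hist.mean_deg,
            "phase_resultant_length": hist.resultant_length,
            "regression": {"slope": slope, "intercept": intercept, "r": r, "p": p},
            "sta_dilution": sta_summary,
            "dilution_target_hz": target,
        },
    )

    # --- stage: rates -----------------------------------------------------
    rates = firing_rate.summarize_rates(task_units + osc_units)
    rates.to_csv(res_dir / "rates.csv", index=False)
    firing_rate.group_summary(rates).to_csv(res_dir / "rates_groups.csv", index=False)
    firing_rate.percent_change(rates).to_csv(
        res_dir / "rates_percent_change.csv", index=False
    )

    # --- stage: report ----------------------------------------------------
    _make_figures(res_dir, fig_dir)
    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(res_dir.rglob("*"))
            if p.is_file()
        },
        "versions": {"numpy": np.__version__},
    }
    _write_json(out / "manifest.json", manifest)
    return out


def _make_figures(res_dir: Path, fig_dir: Path) -> None:
    """Summary figures regenerated purely from the stage output files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    bal = pd.read_csv(res_dir / "balance.csv")
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(bal["t"], bal["id_balance"], lw=1)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time from cue onset (s)")
    ax.set_ylabel("I/D balance")
    fig.tight_layout()
    fig.savefig(fig_dir / "id_balance.png", dpi=100)
    plt.close(fig)

    spectra = json.loads((res_dir / "spectra_summary.json").read_text())
    if spectra["mua_envelope"]:
        labels = sorted(spectra["mua_envelope"])
        zs = [spectra["mua_envelope"][k]["z"] for k in labels]
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.bar(range(len(labels)), zs)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_ylabel("8-15 Hz peak z")
        fig.tight_layout()
        fig.savefig(fig_dir / "psd_peak_z.png", dpi=100)
        plt.close(fig)

    syncs = json.loads((res_dir / "sync_summary.json").read_text())
    labels = sorted(syncs["per_unit"])
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(range(len(labels)), [syncs["per_unit"][k]["peak_coh"] for k in labels])
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("coherence peak (8-15 Hz)")
    fig.tight_layout()
    fig.savefig(fig_dir / "coherence_peaks.png", dpi=100)
    plt.close(fig)
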