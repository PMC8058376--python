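"""Study-emulation orchestration: simulate, analyze, report.

``run_simulate`` writes a synthetic cohort to disk with a manifest;
``run_analyze`` runs every manifest recording through the conditioning →
spectral → index chain and writes tidy CSV tables; ``run_report``
summarizes indices per phase (mean ± SD with Tukey letters, the shape of
the published acute-phase table) and runs the ANOVA/Tukey families.
All outputs are deterministic given the configuration seed: files carry
no timestamps and floats are formatted with a fixed precision.
"""

from __future__ import annotations

import logging
import os
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import indices as idx
from . import preprocess as pre
from . import spectral as spec
from . import stats as st
from . import synthetic_data as synth
from .errors import ParameterError, QeegError
from .io_signals import (PHASE_DURATIONS_S, PhaseLabel, Recording,
                         read_recording, write_recording)

log = logging.getLogger("qeeg_mcao")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated bundle of every knob the pipeline exposes."""

    # study design
    groups: tuple[str, ...] = ("sham", "mcao")
    n_per_group: int = 6
    phases: tuple[str, ...] = tuple(PHASE_DURATIONS_S)
    seed: int = 0
    rate_hz: float = 1000.0
    jitter_sigma: float = synth.DEFAULT_JITTER_SIGMA
    # preprocessing
    highpass_hz: float = pre.DEFAULT_HIGHPASS_HZ
    epoch_s: float = pre.DEFAULT_EPOCH_S
    artifact_uv: float = pre.DEFAULT_ARTIFACT_UV
    # spectral estimation
    seg_s: float = spec.DEFAULT_SEG_S
    overlap_frac: float = spec.DEFAULT_OVERLAP_FRAC
    # classification thresholds
    dar_threshold: float = idx.DAR_THRESHOLD
    dtabr_threshold: float = idx.DTABR_THRESHOLD
    # I/O
    outdir: str = "qeeg_out"
    recording_format: str = "edf"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in self.phases:
            if kind not in PHASE_DURATIONS_S:
                raise ParameterError(f"unknown phase {kind!r} in config")
        if self.recording_format not in ("edf", "delimited"):
            raise ParameterError(f"unknown recording format {self.recording_format!r}")
        if not 0 < self.highpass_hz < self.rate_hz / 2:
            raise ParameterError("highpass_hz must lie in (0, Nyquist)")
        if self.seg_s > self.epoch_s:
            raise ParameterError("seg_s must not exceed epoch_s")
        if 1.0 / self.seg_s > spec.MAX_RESOLUTION_HZ:
            raise ParameterError("seg_s too short to resolve the 1 Hz band edge")
        if not 0 <= self.overlap_frac < 1:
            raise ParameterError("overlap_frac must be in [0, 1)")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if min(self.dar_threshold, self.dtabr_threshold) <= 0:
            raise ParameterError("thresholds must be > 0")

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "PipelineConfig":
        """Load a flat or sectioned TOML config; keyword overrides win."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # sections are flattened by key
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in flat.items() if k in known}
        kwargs["extra"] = {k: v for k, v in flat.items() if k not in known}
        for k in ("groups", "phases"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        kwargs.update(overrides)
        return cls(**kwargs)

    def design(self) -> synth.StudyDesign:
        return synth.StudyDesign(
            groups=self.groups, n_per_group=self.n_per_group,
            phases=tuple(PhaseLabel.of(k) for k in self.phases), seed=self.seed)


def analyze_recording(rec: Recording, cfg: PipelineConfig | None = None
                      ) -> tuple[spec.BandPowerSet, idx.QeegIndices, spec.PowerSpectrum]:
    """Full per-session chain: high-pass → epoch → artifact rejection →
    Welch PSD → band powers → classified indices."""
    if cfg is None:
        cfg = PipelineConfig()
    filtered = pre.highpass_filter(rec, cfg.highpass_hz)
    es = pre.epoch(filtered, cfg.epoch_s)
    es = pre.reject_artifacts(es, cfg.artifact_uv)
    ps = spec.compute_psd(es, cfg.seg_s, cfg.overlap_frac)
    bp = spec.relative_bandpower(ps)
    qi = idx.classify_ischemia(idx.compute_indices(bp),
                               cfg.dar_threshold, cfg.dtabr_threshold)
    return bp, qi, ps


def run_simulate(cfg: PipelineConfig) -> str:
    """Generate the synthetic cohort and write it plus a manifest CSV.

    Returns the manifest path.  Layout: ``<outdir>/recordings/*.{edf,csv}``
    and ``<outdir>/manifest.csv`` (animal,group,phase,file,seed).
    """
    design = cfg.design()
    presets = synth.phase_presets(cfg.jitter_sigma)
    for kind in cfg.phases:
        if kind not in presets and "mcao" in cfg.groups:
            raise ParameterError(f"no preset for phase {kind!r}")
    rec_dir = os.path.join(cfg.outdir, "recordings")
    os.makedirs(rec_dir, exist_ok=True)
    log.info("simulating cohort: seed=%d, %d recordings, preset table v%s",
             design.seed, design.n_recordings, synth.PRESET_VERSION)
    ext = "edf" if cfg.recording_format == "edf" else "csv"
    rows = []
    for rec in synth.generate_cohort(design, presets, rate_hz=cfg.rate_hz):
        fname = f"{rec.animal_id}_{rec.phase.phase_kind}.{ext}"
        write_recording(rec, os.path.join(rec_dir, fname), cfg.recording_format)
        rows.append({"animal": rec.animal_id, "group": rec.group,
                     "phase": rec.phase.phase_kind,
                     "file": os.path.join("recordings", fname), "seed": design.seed})
    manifest = os.path.join(cfg.outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    log.info("wrote %d recordings and %s", len(rows), manifest)
    return manifest


def run_analyze(cfg: PipelineConfig, manifest_path: str
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every manifest recording.

    Writes ``bandpower.csv`` (animal,group,phase,band,abs_power,rel_power),
    ``indices.csv`` (animal,group,phase,dtr,dar,dtabr,dar_ischemic,
    dtabr_ischemic) and one frequency-distribution CSV per (group, phase).
    Unreadable recordings are reported and skipped; the run continues.
    """
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ParameterError(f"empty manifest {manifest_path}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    bp_rows, qi_rows, failures = [], [], []
    freq_acc: dict[tuple[str, str], list[np.ndarray]] = {}
    freq_grid: dict[tuple[str, str], np.ndarray] = {}
    for row in manifest.itertuples(index=False):
        path = os.path.join(base, row.file)
        try:
            rec = read_recording(path)
            bp, qi, ps = analyze_recording(rec, cfg)
        except (QeegError, OSError) as exc:
            failures.append(f"{path}: {exc}")
            log.error("skipping %s: %s", path, exc)
            continue
        for band in spec.COMPONENT_BANDS:
            bp_rows.append({"animal": row.animal, "group": row.group,
                            "phase": row.phase, "band": band,
                            "abs_power": bp.absolute[band],
                            "rel_power": bp.relative[band]})
        qi_rows.append({"animal": row.animal, "group": row.group, "phase": row.phase,
                        "dtr": qi.dtr, "dar": qi.dar, "dtabr": qi.dtabr,
                        "dar_ischemic": qi.dar_ischemic,
                        "dtabr_ischemic": qi.dtabr_ischemic})
        key = (str(row.group), str(row.phase))
        fd = spec.frequency_distribution(ps)
        freq_acc.setdefault(key, []).append(fd["psd_uv2_per_hz"].to_numpy())
        freq_grid[key] = fd["freq_hz"].to_numpy()
    if not qi_rows:
        raise ParameterError("no recording could be analyzed; failures: "
                             + "; ".join(failures))
    if failures:
        log.warning("%d recording(s) skipped: %s", len(failures), "; ".join(failures))
    os.makedirs(cfg.outdir, exist_ok=True)
    bandpower = pd.DataFrame(bp_rows)
    index_table = pd.DataFrame(qi_rows)
    bandpower.to_csv(os.path.join(cfg.outdir, "bandpower.csv"),
                     index=False, float_format=_FLOAT_FMT)
    index_table.to_csv(os.path.join(cfg.outdir, "indices.csv"),
                       index=False, float_format=_FLOAT_FMT)
    fd_dir = os.path.join(cfg.outdir, "frequency_distribution")
    os.makedirs(fd_dir, exist_ok=True)
    for (group, phase), curves in sorted(freq_acc.items()):
        table = pd.DataFrame({"freq_hz": freq_grid[(group, phase)],
                              "psd_uv2_per_hz": np.mean(curves, axis=0)})
        table.to_csv(os.path.join(fd_dir, f"{group}_{phase}.csv"),
                     index=False, float_format=_FLOAT_FMT)
    return bandpower, index_table


def _acute_index_summary(index_table: pd.DataFrame) -> pd.DataFrame:
    """Per-phase mean ± SD of each index with Tukey letters, over the
    occluded group's acute phases (anesthetized control, ISP, IRP)."""
    acute = [p for p in ("anesthetized", "isp", "irp")
             if p in set(index_table["phase"])]
    sub = index_table[(index_table["group"] == "mcao")
                      & index_table["phase"].isin(acute)]
    rows = []
    for name in ("dtr", "dar", "dtabr"):
        by_phase = {p: sub.loc[sub["phase"] == p, name].to_numpy() for p in acute}
        by_phase = {p: v for p, v in by_phase.items() if v.size >= 2}
        if len(by_phase) >= 2:
            gs = st.summarize_groups(by_phase)
            for lab, n, mean, sd, letters in zip(gs.labels, gs.n, gs.mean, gs.sd, gs.letters):
                rows.append({"phase": lab, "index": name, "n": n,
                             "mean": mean, "sd": sd, "letters": letters})
    return pd.DataFrame(rows)


def _subacute_band_summary(bandpower: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily relative band power, occluded days vs sham control.

    The control group is each sham animal's mean over the daily sessions
    (one value per animal), compared against the occluded group's D1-D7
    by one-way ANOVA + Tukey per band (8 groups).
    """
    days = [f"d{i}" for i in range(1, 8) if f"d{i}" in set(bandpower["phase"])]
    summary_rows, anova_rows = [], []
    if not days:
        return pd.DataFrame(summary_rows), pd.DataFrame(anova_rows)
    for band in spec.COMPONENT_BANDS[:4]:
        sel = bandpower[bandpower["band"] == band]
        sham = sel[(sel["group"] == "sham") & sel["phase"].isin(days)]
        groups: dict[str, np.ndarray] = {}
        if not sham.empty:
            groups["control"] = sham.groupby("animal")["rel_power"].mean().to_numpy()
        for d in days:
            vals = sel.loc[(sel["group"] == "mcao") & (sel["phase"] == d),
                           "rel_power"].to_numpy()
            if vals.size:
                groups[d] = vals
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        an = st.one_way_anova(list(groups.values()))
        anova_rows.append({"family": f"subacute_{band}", "effect": "group",
                           "f": an.f_value, "df1": an.df_between,
                           "df2": an.df_within, "p": an.p_value})
        gs = st.summarize_groups(groups)
        for lab, n, mean, sd, letters in zip(gs.labels, gs.n, gs.mean, gs.sd, gs.letters):
            summary_rows.append({"band": band, "group": lab, "n": n,
                                 "mean": mean, "sd": sd, "letters": letters})
    return pd.DataFrame(summary_rows), pd.DataFrame(anova_rows)


def run_report(cfg: PipelineConfig, bandpower: pd.DataFrame,
               index_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables and the statistical report.

    Writes ``acute_indices_summary.csv`` (phase,index,mean,sd,letters),
    ``subacute_bandpower_summary.csv``, ``anova.csv``, ``tukey.csv`` and a
    plain-text ``report.txt``; returns the tables.
    """
    counts = index_table.groupby(["group", "phase"])["animal"].nunique()
    if (counts < 2).any():
        raise ParameterError("fewer than 2 animals in some group/phase: "
                             f"{counts[counts < 2].to_dict()}")
    acute = _acute_index_summary(index_table)
    sub_summary, sub_anova = _subacute_band_summary(bandpower)

    anova_rows, tukey_rows = list(sub_anova.to_dict("records")), []
    acute_phases = [p for p in ("anesthetized", "isp", "irp")
                    if p in set(index_table["phase"])]
    mcao = index_table[(index_table["group"] == "mcao")
                       & index_table["phase"].isin(acute_phases)]
    for name in ("dtr", "dar", "dtabr"):
        groups = {p: mcao.loc[mcao["phase"] == p, name].to_numpy()
                  for p in acute_phases}
        groups = {p: v for p, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        an = st.one_way_anova(list(groups.values()))
        anova_rows.append({"family": f"acute_{name}", "effect": "phase",
                           "f": an.f_value, "df1": an.df_between,
                           "df2": an.df_within, "p": an.p_value})
        tk = st.tukey_hsd(list(groups.values()), labels=list(groups))
        for pair, diff, q, p_adj in zip(tk.pairs, tk.diffs, tk.q, tk.p_adj):
            tukey_rows.append({"family": f"acute_{name}",
                               "pair": f"{pair[0]}-{pair[1]}",
                               "diff": diff, "q": q, "p_adj": p_adj})

    os.makedirs(cfg.outdir, exist_ok=True)
    tables = {
        "acute_indices_summary": acute,
        "subacute_bandpower_summary": sub_summary,
        "anova": pd.DataFrame(anova_rows),
        "tukey": pd.DataFrame(tukey_rows),
    }
    for name, table in tables.items():
        table.to_csv(os.path.join(cfg.outdir, f"{name}.csv"),
                     index=False, float_format=_FLOAT_FMT)

    flagged = index_table[index_table["dar_ischemic"] | index_table["dtabr_ischemic"]]
    lines = [
        "qEEG ischemia-reperfusion report",
        f"seed: {cfg.seed}    preset table: v{synth.PRESET_VERSION}",
        f"sessions analyzed: {len(index_table)}",
        f"threshold crossings (DAR > {cfg.dar_threshold:g} or "
        f"DTABR > {cfg.dtabr_threshold:g}): {len(flagged)}",
        "",
        "Acute-phase indices (mean +/- SD, shared letters = not significantly different):",
    ]
    for _, row in acute.iterrows():
        lines.append(f"  {row['phase']:>12} {row['index'].upper():>6} "
                     f"{row['mean']:8.2f} +/- {row['sd']:.2f}  [{row['letters']}]")
    lines.append("")
    for row in anova_rows:
        lines.append(f"  ANOVA {row['family']}: F({row['df1']},{row['df2']}) = "
                     f"{row['f']:.2f}, p = {row['p']:.4g}")
    with open(os.path.join(cfg.outdir, "report.txt"), "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return tables


def run_all(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """simulate → analyze → report with one configuration."""
    manifest = run_simulate(cfg)
    bandpower, index_table = run_analyze(cfg, manifest)
    return run_report(cfg, bandpower, index_table)
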