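"""Ground-truth-known synthetic datasets emulating the greenhouse study.

The generator emulates the structure of the real experiments: a
time-series experiment (2-hourly leaf sampling over 24 h, at one-week
intervals for several weeks, two cultivars, two replicates -> 192 samples
at the default sizes) and optional snapshot experiments sampled around
noon on a couple of dates with batch shifts, more cultivars and different
rate levels.

Latent metabolite contents are built on a z-scale and then expressed in
per-metabolite z-score units:

    z_ij  proportional to  lambda_j f_{b(j)}(i)      (co-regulated module factor)
                         + m_j(cell(i))              (per-metabolite cell effect)
                         + A_j sin(2 pi (hour_i - phi_j)/24)   (diurnal rhythm)
                         + delta_j(experiment_i)     (batch shift)
                         + sigma_met eps_ij          (per-sample variation),

scaled so each metabolite has unit latent SD; a "cell" is one
(experiment, cultivar, sampling date).  The bulk (non-predictor)
metabolome is organized into a few strongly co-regulated modules, while
the phenotype-linked metabolites each carry mostly distinct per-sample
information -- the redundancy of the bulk is what makes a sparse panel
identifiable at the study's sample size.  Peak areas are exp-transformed
positive contents times the internal-standard area with multiplicative
measurement noise, so areas are nonnegative and right-skewed.  Extra
blank-dominated compounds are appended so the detection filter has true
negatives, and two internal-standard columns are included.

The anthesis rate is linear in a sparse metabolite subset S with effect
sizes in rate units per SD: ``rate_linkage='weekly'`` (default, mirroring
the study's pairing) links the rate of a cell to the weekly mean contents
z-bar_j(cell) and broadcasts it to every leaf sample of that cell;
``rate_linkage='sample'`` links y_i directly to z_ij, giving one
informative response per sample (the regime used for support-recovery
benchmarking).  Unless an explicit rate noise SD is given, it is
calibrated so the generative model explains ``target_r2`` of the rate
variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PeakTable, META_COLUMNS


class SpecError(ValueError):
    """Invalid synthetic-data specification; the message names the field."""


@dataclass(frozen=True)
class ExperimentSpec:
    """One greenhouse experiment within a synthetic study."""

    label: str
    kind: str = "timeseries"            # 'timeseries' | 'snapshot'
    batch_shift: float = 0.0            # z-score units, per-metabolite SD
    rate_offset: float = 0.0            # flowers/week added to the intercept
    cultivars: tuple[str, ...] | None = None  # None -> SyntheticSpec.cultivars
    replicates: int = 2
    start_date: str = "2016-08-16"
    n_dates: int = 2                    # snapshot experiments only
    date_spacing_days: int = 14         # snapshot experiments only


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the time-series
    experiment at the study's scale (4 weeks x 12 timepoints x 2 cultivars
    x 2 replicates = 192 samples, 161 detected metabolites, 29-sparse
    phenotype support)."""

    n_weeks: int = 4
    timepoints_per_day: int = 12        # sampling every 2 h
    cultivars: tuple[str, ...] = ("Ringyoku", "CFMY")
    experiments: tuple[ExperimentSpec, ...] = (
        ExperimentSpec(label="TK01", kind="timeseries"),
    )
    m_metabolites: int = 161            # truly detectable compounds
    n_undetected: int = 40              # blank-dominated compounds (filter negatives)
    n_blocks: int = 6                   # co-regulated latent modules
    support_indices: tuple[int, ...] | None = None   # None -> 29 spread indices
    beta: tuple[float, ...] | None = None            # None -> alternating-sign ramp
    intercept_rate: float = 7.0         # flowers/week
    rate_trend: float = 0.3             # weekly decline, flowers/week per week
    diurnal_amplitudes: tuple[float, ...] | None = None  # None -> drawn per metabolite
    noise_sd_metabolite: float = 1.0    # z-units, per-sample idiosyncratic variation
    noise_sd_rate: float | None = None  # flowers/week; None -> calibrated to target_r2
    target_r2: float = 0.85
    block_loading: float = 8.0          # relative module weight, bulk metabolites
    block_loading_support: float = 0.0  # relative module weight, phenotype-linked
    cell_effect_sd: float = 0.3         # relative weight of m_j(cell)
    latent_scale: float = 0.3           # z-score -> log relative content
    is_response_factor: float = 0.05    # relative content at z = 0
    blank_level: float = 100.0          # mean blank peak area
    is_area: float = 1.0e4              # internal-standard peak area
    measurement_cv: float = 0.02        # lognormal sigma on peak areas
    rate_linkage: str = "weekly"        # 'weekly' | 'sample'
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_weeks", "timepoints_per_day", "m_metabolites", "n_blocks"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be >= 1")
        if self.n_undetected < 0:
            raise SpecError("n_undetected must be >= 0")
        for name in ("noise_sd_metabolite", "blank_level", "is_response_factor",
                     "is_area", "block_loading", "cell_effect_sd"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be nonnegative")
        if self.is_response_factor <= 0:
            raise SpecError("is_response_factor must be positive")
        if self.noise_sd_rate is not None and self.noise_sd_rate < 0:
            raise SpecError("noise_sd_rate must be nonnegative")
        if not 0 < self.target_r2 < 1:
            raise SpecError("target_r2 must lie in (0, 1)")
        if self.rate_linkage not in ("weekly", "sample"):
            raise SpecError("rate_linkage must be 'weekly' or 'sample'")
        if self.support_indices is not None:
            s = tuple(int(j) for j in self.support_indices)
            if any(j < 0 or j >= self.m_metabolites for j in s):
                raise SpecError("support_indices must lie in [0, m_metabolites)")
            if len(set(s)) != len(s):
                raise SpecError("support_indices must be unique")
            setattr(self, "support_indices", s)
        if self.diurnal_amplitudes is not None:
            amps = tuple(float(a) for a in self.diurnal_amplitudes)
            if len(amps) != self.m_metabolites:
                raise SpecError("diurnal_amplitudes must have m_metabolites entries")
            if any(a < 0 for a in amps):
                raise SpecError("diurnal_amplitudes must be nonnegative")
            setattr(self, "diurnal_amplitudes", amps)
        if self.beta is not None and self.support_indices is not None:
            if len(self.beta) != len(self.support_indices):
                raise SpecError("beta must match support_indices in length")

    @classmethod
    def full_study(cls, seed: int = 0, **kwargs) -> "SyntheticSpec":
        """The three-experiment layout: a TK01-like time series plus two
        batch-shifted snapshot experiments with extra cultivars and higher
        anthesis rates."""
        experiments = (
            ExperimentSpec(label="TK01", kind="timeseries"),
            ExperimentSpec(label="IA04", kind="snapshot", batch_shift=0.8,
                           rate_offset=1.0,
                           cultivars=("CFMY", "C5-159", "C5-160", "C6-164"),
                           replicates=3, start_date="2016-10-13"),
            ExperimentSpec(label="IA06", kind="snapshot", batch_shift=1.2,
                           rate_offset=2.5,
                           cultivars=("CFMY", "Ringyoku", "Managua"),
                           replicates=7, start_date="2017-01-19"),
        )
        return cls(experiments=experiments, seed=seed, **kwargs)

    def default_support(self) -> tuple[int, ...]:
        if self.support_indices is not None:
            return self.support_indices
        step = max(1, self.m_metabolites // 29)
        idx = tuple(range(0, step * 29, step))[:29]
        return tuple(j for j in idx if j < self.m_metabolites)

    def default_beta(self, support: tuple[int, ...]) -> np.ndarray:
        if self.beta is not None:
            return np.asarray(self.beta, dtype=float)
        s = len(support)
        signs = np.where(np.arange(s) % 2 == 0, 1.0, -1.0)
        beta = 0.55 * signs
        # the designated stable marker carries the largest positive weight
        beta[0] = 0.9
        return beta


ENV_COLUMNS = ["solar_irradiance", "temperature", "relative_humidity", "co2"]


def _metabolite_names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    detected = [f"met_{j + 1:03d}" for j in range(spec.m_metabolites)]
    undetected = [f"und_{j + 1:03d}" for j in range(spec.n_undetected)]
    standards = ["IS_lido", "IS_camphor"]
    return detected, undetected, standards


def _sample_grid(spec: SyntheticSpec) -> pd.DataFrame:
    """Enumerate all samples of all experiments with their metadata."""
    rows = []
    for exp in spec.experiments:
        cultivars = exp.cultivars if exp.cultivars is not None else spec.cultivars
        base = pd.Timestamp(exp.start_date)
        if exp.kind == "timeseries":
            hours = [24 // spec.timepoints_per_day * t for t in range(spec.timepoints_per_day)]
            for week in range(spec.n_weeks):
                day = base + pd.Timedelta(days=7 * week)
                for cultivar in cultivars:
                    for hour in hours:
                        for rep in range(1, exp.replicates + 1):
                            rows.append((exp.label, cultivar, day, week, hour, rep))
        elif exp.kind == "snapshot":
            for d in range(exp.n_dates):
                day = base + pd.Timedelta(days=exp.date_spacing_days * d)
                for cultivar in cultivars:
                    for rep in range(1, exp.replicates + 1):
                        rows.append((exp.label, cultivar, day, d, 12, rep))
        else:
            raise SpecError(f"experiments: unknown kind {exp.kind!r}")
    df = pd.DataFrame(rows, columns=["experiment", "cultivar", "date", "week", "hour", "replicate"])
    df["datetime"] = df["date"] + pd.to_timedelta(df["hour"], unit="h")
    df["plant"] = (df["experiment"] + "-" + df["cultivar"] + "-p"
                   + df["replicate"].astype(str))
    df["sample_id"] = (df["experiment"] + "_" + df["cultivar"] + "_"
                       + df["date"].dt.strftime("%Y%m%d") + "_h"
                       + df["hour"].astype(str).str.zfill(2) + "_r"
                       + df["replicate"].astype(str))
    df["cell"] = df["experiment"] + ":" + df["cultivar"] + ":" + df["date"].dt.strftime("%Y%m%d")
    df["group"] = df["experiment"] + ":" + df["cultivar"]
    return df


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[PeakTable, pd.DataFrame, dict, pd.DataFrame]:
    """Generate a PeakTable, a long anthesis table (group, date,
    cumulative_count), a ground-truth record, and an environmental table.

    Identical spec and seed give identical output (and, through
    ``write_dataset``, byte-identical files).
    """
    rng = np.random.default_rng(spec.seed)
    detected, undetected, standards = _metabolite_names(spec)
    m = spec.m_metabolites
    support = spec.default_support()
    beta = spec.default_beta(support)
    marker_id = detected[support[0]]

    # per-metabolite latent structure -------------------------------------
    if spec.diurnal_amplitudes is not None:
        amplitudes = np.asarray(spec.diurnal_amplitudes, dtype=float)
    else:
        amplitudes = rng.uniform(0.2, 0.9, size=m)
        stable = rng.random(m) < 0.3          # near-flat "stable" metabolites
        amplitudes[stable] = rng.uniform(0.0, 0.1, size=int(stable.sum()))
    amplitudes = amplitudes.copy()
    amplitudes[support[0]] = 0.0              # the marker has no diurnal rhythm
    phases = rng.uniform(0, 24, size=m)
    blocks = np.arange(m) % spec.n_blocks

    grid = _sample_grid(spec)
    n = len(grid)
    cells = grid["cell"].to_numpy()
    cell_ids, cell_inverse = np.unique(cells, return_inverse=True)
    n_cells = len(cell_ids)

    shifts = {}
    for exp in spec.experiments:
        shifts[exp.label] = (rng.normal(0.0, exp.batch_shift, size=m)
                             if exp.batch_shift > 0 else np.zeros(m))
    shift_rows = np.stack([shifts[e] for e in grid["experiment"]])

    block_factor = rng.normal(size=(n, spec.n_blocks))
    cell_effect = rng.normal(0.0, spec.cell_effect_sd, size=(n_cells, m))
    noise = rng.normal(0.0, spec.noise_sd_metabolite, size=(n, m))

    hours = grid["hour"].to_numpy(dtype=float)[:, None]
    diurnal = amplitudes[None, :] * np.sin(2 * np.pi * (hours - phases[None, :]) / 24.0)
    # the bulk metabolome is strongly co-regulated (modular blocks); the
    # phenotype-linked metabolites each carry mostly distinct information
    loadings = np.full(m, spec.block_loading)
    loadings[list(support)] = spec.block_loading_support
    z_raw = (loadings[None, :] * block_factor[:, blocks]
             + cell_effect[cell_inverse]
             + shift_rows
             + noise
             + diurnal)
    # per-metabolite z-score units: scale by the theoretical SD so effect
    # sizes are rate units per SD and every compound spans a comparable
    # (modest) dynamic range on the content scale
    sd_theo = np.sqrt(loadings ** 2 + spec.cell_effect_sd ** 2
                      + amplitudes ** 2 / 2 + spec.noise_sd_metabolite ** 2)
    z = z_raw / sd_theo[None, :]

    # anthesis rates ------------------------------------------------------
    week = grid["week"].to_numpy(dtype=float)
    offsets = {e.label: e.rate_offset for e in spec.experiments}
    base_rate = (spec.intercept_rate
                 + np.array([offsets[e] for e in grid["experiment"]])
                 - spec.rate_trend * week)
    if spec.rate_linkage == "weekly":
        zbar = np.zeros((n_cells, len(support)))
        counts = np.bincount(cell_inverse, minlength=n_cells).astype(float)
        for s_pos, j in enumerate(support):
            zbar[:, s_pos] = np.bincount(cell_inverse, weights=z[:, j],
                                         minlength=n_cells) / counts
        signal = base_rate + (zbar @ beta)[cell_inverse]
    else:
        signal = base_rate + z[:, list(support)] @ beta

    if spec.noise_sd_rate is None:
        sd = float(np.std(signal))
        noise_sd_rate = sd * np.sqrt((1 - spec.target_r2) / spec.target_r2)
    else:
        noise_sd_rate = float(spec.noise_sd_rate)

    if spec.rate_linkage == "weekly":
        eps_cell = rng.normal(0.0, noise_sd_rate, size=n_cells)
        y = signal + eps_cell[cell_inverse]
    else:
        y = signal + rng.normal(0.0, noise_sd_rate, size=n)
    y = np.maximum(y, 0.0)

    # cell-level rates for the anthesis table (means within cells)
    counts = np.bincount(cell_inverse, minlength=n_cells).astype(float)
    cell_rate = np.bincount(cell_inverse, weights=y, minlength=n_cells) / counts

    # peak areas ----------------------------------------------------------
    rel_content = spec.is_response_factor * np.exp(spec.latent_scale * z)
    is1 = spec.is_area * np.exp(rng.normal(0.0, spec.measurement_cv, size=n))
    is2 = 0.4 * spec.is_area * np.exp(rng.normal(0.0, spec.measurement_cv, size=n))
    meas = np.exp(rng.normal(0.0, spec.measurement_cv, size=(n, m)))
    areas_detected = rel_content * is1[:, None] * meas

    und = (0.9 * spec.blank_level
           * np.exp(rng.normal(0.0, 0.3, size=(n, spec.n_undetected))))
    und[rng.random((n, spec.n_undetected)) < 0.10] = 0.0   # below detection limit

    area_cols = {}
    for j, name in enumerate(detected):
        area_cols[name] = areas_detected[:, j]
    for j, name in enumerate(undetected):
        area_cols[name] = und[:, j]
    area_cols[standards[0]] = is1
    area_cols[standards[1]] = is2
    areas = pd.DataFrame(area_cols, index=grid["sample_id"])

    compound_ids = detected + undetected + standards
    blank = pd.DataFrame(
        spec.blank_level * np.exp(rng.normal(0.0, 0.2, size=(len(compound_ids), 3))),
        index=pd.Index(compound_ids, name="compound"),
        columns=["blank_1", "blank_2", "blank_3"],
    )
    # internal standards barely leach into blanks
    blank.loc[standards] = spec.blank_level * 0.01

    meta = grid[META_COLUMNS].copy()
    meta.index = grid["sample_id"]
    meta["datetime"] = meta["datetime"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    table = PeakTable(areas, blank, tuple(standards), meta)

    # anthesis table ------------------------------------------------------
    anthesis_rows = []
    cell_frame = grid.drop_duplicates("cell").set_index("cell")
    for group, sub in cell_frame.groupby("group", sort=True):
        sub = sub.sort_values("date")
        dates = list(sub["date"])
        rates = [cell_rate[np.flatnonzero(cell_ids == c)[0]] for c in sub.index]
        spacing = (dates[1] - dates[0]) if len(dates) > 1 else pd.Timedelta(days=7)
        start = dates[0] - spacing
        cum = 10.0
        anthesis_rows.append((group, start.strftime("%Y-%m-%d"), cum))
        prev = start
        for d, r in zip(dates, rates):
            cum += r * (d - prev).days / 7.0
            anthesis_rows.append((group, d.strftime("%Y-%m-%d"), cum))
            prev = d
    anthesis = pd.DataFrame(anthesis_rows, columns=["group", "date", "cumulative_count"])

    # environmental factors: uninformative covariates around typical values
    env = pd.DataFrame(
        {
            "solar_irradiance": 500 + 120 * rng.standard_normal(n),
            "temperature": 25 + 3 * rng.standard_normal(n),
            "relative_humidity": 72 + 6 * rng.standard_normal(n),
            "co2": 520 + 80 * rng.standard_normal(n),
        },
        index=grid["sample_id"],
    )

    ground_truth = {
        "support_ids": [detected[j] for j in support],
        "support_indices": [int(j) for j in support],
        "beta": [float(b) for b in beta],
        "marker_id": marker_id,
        "diurnal_amplitudes": {detected[j]: float(amplitudes[j]) for j in range(m)},
        "noise_sd_rate": noise_sd_rate,
        "rate_linkage": spec.rate_linkage,
        "seed": spec.seed,
        "sample_rates": {sid: float(v) for sid, v in zip(grid["sample_id"], y)},
        "cell_rates": {str(c): float(r) for c, r in zip(cell_ids, cell_rate)},
        "n_samples": int(n),
    }
    return table, anthesis, ground_truth, env


def write_dataset(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Write peaks.csv, blanks.csv, anthesis.csv, environment.csv and
    ground_truth.json under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, anthesis, truth, env = generate_dataset(spec)
    paths = {
        "peaks": out / "peaks.csv",
        "blanks": out / "blanks.csv",
        "anthesis": out / "anthesis.csv",
        "environment": out / "environment.csv",
        "ground_truth": out / "ground_truth.json",
    }
    peaks = pd.concat([table.sample_meta.reset_index(drop=True),
                       table.areas.reset_index(drop=True)], axis=1)
    peaks.to_csv(paths["peaks"], index=False, float_format="%.8g")
    table.blank_areas.to_csv(paths["blanks"], float_format="%.8g")
    anthesis.to_csv(paths["anthesis"], index=False, float_format="%.8g")
    env.to_csv(paths["environment"], float_format="%.8g")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def spec_from_yaml(path) -> SyntheticSpec:
    """Load a SyntheticSpec (with nested experiment blocks) from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    experiments = raw.pop("experiments", None)
    kwargs = dict(raw)
    for key in ("cultivars", "support_indices", "beta", "diurnal_amplitudes"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if experiments is not None:
        exps = []
        for e in experiments:
            if e.get("cultivars") is not None:
                e["cultivars"] = tuple(e["cultivars"])
            exps.append(ExperimentSpec(**e))
        kwargs["experiments"] = tuple(exps)
    return SyntheticSpec(**kwargs)
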