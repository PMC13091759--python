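"""End-to-end pipeline: simulate -> fit -> markers -> analyze -> repeatability.

Everything is driven by a :class:`PipelineConfig` (YAML-serialisable, every
constant defaulting to the study design: 14 levels, 4% easy trials, conflict at
1.5 JND, lapse bounded by [0, 0.2], PSE bounded by [-1, 1]) and a single seed;
identical config + seed reproduce byte-identical CSV outputs.  CSV is the sole
interchange format.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DepthDesign
from .group import analyze_metrics, detect_inverse_mapping, render_report
from .metrics import metrics_from_fits
from .observers import DEFAULT_SESSION_SCHEDULE, PopulationSpec, simulate_study
from .power import power_grid
from .psychofit import GridSpec, fit_trial_table
from .repeatability import repeatability_table

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture",
           "write_trials", "read_trials"]

log = logging.getLogger("cuecombine")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
log.setLevel(logging.INFO)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the pipeline; defaults reproduce the study design."""

    seed: int = 0
    # population
    n_participants: int = 12
    mean_sigma_D: float = 0.2
    mean_sigma_S: float = 0.3
    mean_sigma_A: float = 0.3
    between_sd: float = 0.05
    within_sd: float = 0.02
    sigma_Du_factor: float = 2.0
    lapse_low: float = 0.0
    lapse_high: float = 0.06
    strategy: str = "optimal"
    switch_p: float | None = None
    binds_novel_cue: bool = True
    # design
    n_trials_per_condition: int = 150
    easy_trial_rate: float = 0.04
    conflict_jnd_multiple: float = 1.5
    sessions: dict = field(default_factory=lambda: {
        int(k): list(v) for k, v in DEFAULT_SESSION_SCHEDULE.items()})
    # fitting grid bounds
    beta_bounds: tuple = (0.02, 200.0)
    alpha_bounds: tuple = (-1.0, 1.0)
    lam_bounds: tuple = (0.0, 0.2)
    n_beta: int = 301
    n_alpha: int = 61
    n_lam: int = 21
    exclude_easy: bool = True
    # analysis toggles
    run_repeatability: bool = True
    n_boot: int = 500
    n_perm: int = 0
    run_power: bool = False
    power_sigma_best: tuple = (0.2,)
    power_ratios: tuple = (1.5,)
    power_ns: tuple = (30,)
    power_n_sims: int = 1000

    def grid(self) -> GridSpec:
        return GridSpec.make(n_beta=self.n_beta, n_alpha=self.n_alpha,
                             n_lam=self.n_lam, beta_bounds=tuple(self.beta_bounds),
                             alpha_bounds=tuple(self.alpha_bounds),
                             lam_bounds=tuple(self.lam_bounds))

    def population(self) -> PopulationSpec:
        return PopulationSpec(
            n_participants=self.n_participants, mean_sigma_D=self.mean_sigma_D,
            mean_sigma_S=self.mean_sigma_S, mean_sigma_A=self.mean_sigma_A,
            between_sd=self.between_sd, within_sd=self.within_sd,
            sigma_Du_factor=self.sigma_Du_factor,
            lapse_range=(self.lapse_low, self.lapse_high),
            strategy=self.strategy, switch_p=self.switch_p,
            binds_novel_cue=self.binds_novel_cue,
            conflict_jnd_multiple=self.conflict_jnd_multiple)

    def design(self) -> DepthDesign:
        return DepthDesign(easy_trial_rate=self.easy_trial_rate)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sessions"] = {int(k): list(v) for k, v in d["sessions"].items()}
        for key in ("beta_bounds", "alpha_bounds", "lam_bounds",
                    "power_sigma_best", "power_ratios", "power_ns"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sessions" in d:
            d["sessions"] = {int(k): list(v) for k, v in d["sessions"].items()}
        for key in ("beta_bounds", "alpha_bounds", "lam_bounds",
                    "power_sigma_best", "power_ratios", "power_ns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()


def write_trials(trials: pd.DataFrame, path) -> None:
    """TrialTable CSV: one header row, UTF-8, response coded {0,1}."""
    df = trials.copy()
    df["easy"] = df["easy"].astype(int)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    df["easy"] = df["easy"].astype(bool)
    return df


def _repeatability_input(fits: pd.DataFrame, sessions=(2, 4)) -> pd.DataFrame:
    """Long (participant, session, measure, value) table of sigma per condition
    present in both comparison sessions."""
    df = fits[fits["session"].isin(sessions)].copy()
    counts = df.groupby("condition", observed=True)["session"].nunique()
    repeated = counts[counts == len(sessions)].index
    df = df[df["condition"].isin(repeated)]
    out = pd.DataFrame({
        "participant": df["participant"], "session": df["session"],
        "measure": "sigma_" + df["condition"].astype(str),
        "value": 1.0 / (df["beta"] * np.sqrt(2.0)),
    })
    return out.reset_index(drop=True)


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                log.error("stage %s FAILED after %.1fs: %s", name, dt, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done (%.1fs)", name, dt)
    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full simulate -> fit -> markers -> analyze (-> repeatability,
    -> power) pipeline and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_rep, s_pow = ss.spawn(3)

    with _stage("simulate"):
        trials = simulate_study(config.population(), sessions=config.sessions,
                                design=config.design(),
                                n_trials_per_condition=config.n_trials_per_condition,
                                seed=s_sim)
        write_trials(trials, out / "trials.csv")

    with _stage("fit"):
        fits = fit_trial_table(trials, grid=config.grid(),
                               exclude_easy=config.exclude_easy)
        fits.to_csv(out / "fits.csv", index=False)

    with _stage("markers"):
        metrics = metrics_from_fits(
            fits, conflict_multiple=config.conflict_jnd_multiple)
        metrics.to_csv(out / "metrics.csv", index=False)

    with _stage("analyze"):
        inverse = detect_inverse_mapping(trials)
        results = analyze_metrics(metrics, fits,
                                  inverse_mapping_participants=inverse)
        (out / "report.md").write_text(render_report(results), encoding="utf-8")
        results["exclusions"].entries.to_csv(out / "exclusions.csv", index=False)

    if config.run_repeatability:
        with _stage("repeatability"):
            long = _repeatability_input(fits)
            rep = repeatability_table(long, n_boot=config.n_boot,
                                      n_perm=config.n_perm,
                                      seed=s_rep)
            rep.to_csv(out / "repeatability.csv", index=False)

    if config.run_power:
        with _stage("power"):
            pw = power_grid(config.power_sigma_best, config.power_ratios,
                            config.power_ns, n_sims=config.power_n_sims,
                            seed=s_pow, grid=config.grid())
            pw.to_csv(out / "power.csv", index=False)

    with _stage("manifest"):
        manifest = {
            "package": "cuecombine", "version": __version__,
            "seed": config.seed, "config_sha256": config.digest(),
            "numpy": np.__version__, "pandas": pd.__version__,
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        config.save(out / "config.yaml")
    return out


# ---------------------------------------------------------------------------
# named fixtures (generated deterministically, used by tests and examples)

_FIXTURE_SEEDS = {"optimal_cohort": 101, "switcher_cohort": 202,
                  "messy_cohort": 303}


def make_fixture(name: str, n_participants: int = 8,
                 n_trials_per_condition: int = 120):
    """Small named cohorts with known ground truth.

    * ``optimal_cohort`` — reliability-weighted averagers: positive CI expected.
    * ``switcher_cohort`` — trial-by-trial cue switchers: CI around zero or
      negative, but re-weighting still positive (switch probabilities track
      reliability).
    * ``messy_cohort`` — averagers plus one very noisy disparity observer, one
      high-lapse observer and one inverse audio mapper, exercising every
      exclusion rule.

    Returns ``(trials, info)`` with ``info`` describing the generative setup.
    """
    if name not in _FIXTURE_SEEDS:
        raise KeyError(f"unknown fixture {name!r}; choose from "
                       f"{sorted(_FIXTURE_SEEDS)}")
    seed = _FIXTURE_SEEDS[name]
    strategy = "switching" if name == "switcher_cohort" else "optimal"
    pop = PopulationSpec(n_participants=n_participants, strategy=strategy,
                         between_sd=0.03, within_sd=0.015,
                         lapse_range=(0.0, 0.04))
    sessions = {2: ["D", "S", "A", "DS", "DA", "DS+", "DS-", "DA+", "DA-"],
                3: ["Du", "S", "A", "DuS", "DuA", "DuS+", "DuS-", "DuA+", "DuA-"],
                4: ["D", "S", "A", "DS", "DA", "DSi", "DAi"]}
    trials = simulate_study(pop, sessions=sessions,
                            n_trials_per_condition=n_trials_per_condition,
                            seed=seed)
    info = {"name": name, "seed": seed, "population": pop, "tweaks": []}

    if name == "messy_cohort":
        rng = np.random.default_rng(seed + 1)
        pids = sorted(trials["participant"].unique())
        noisy_pid, lapse_pid, inverse_pid = pids[0], pids[1], pids[2]
        # observer who cannot discriminate disparity: rerandomise D-only responses
        m = trials["condition"].isin(["D", "Du"]) & (trials["participant"] == noisy_pid)
        trials.loc[m, "response"] = rng.integers(0, 2, int(m.sum()))
        # chronically lapsing observer: 20% of all responses replaced
        m = trials["participant"] == lapse_pid
        lapse_rows = m & (rng.random(len(trials)) < 0.20)
        # lapses report "comparison further" regardless (matches the fitted model)
        ref_first = trials.loc[lapse_rows, "reference_interval"] == 1
        trials.loc[lapse_rows, "response"] = ref_first.astype(int)
        # inverse audio mapping: flip the recoded audio responses
        m = (trials["condition"] == "A") & (trials["participant"] == inverse_pid)
        trials.loc[m, "response"] = 1 - trials.loc[m, "response"]
        info["tweaks"] = [("noisy-disparity", noisy_pid),
                         ("high-lapse", lapse_pid),
                         ("inverse-mapping", inverse_pid)]
    return trials, info
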