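"""Synthetic winter-wheat water-stress trial generator.

Emulates the experimental design behind the plot-level band table the
rest of the package consumes: four irrigation treatments (W1-W4, from
severe drought to heavy over-irrigation), ten cultivars × three
replications = 30 plots per treatment, 120 plots in total.  Default
treatment yield means and standard deviations are the observed
descriptive statistics of such a trial (means 7.77/8.32/8.97/8.19
t·ha⁻¹, SDs 1.56/1.39/1.19/1.26 t·ha⁻¹).

Generative model, per plot i in treatment t with cultivar c:

    u_i   ~ N(0, 1)                              (within-treatment canopy vigor)
    yield = mu_t + gamma_c + s_t·(a·u_i + sqrt(1−a²)·e_i),  e_i ~ N(0, 1)

where ``a`` is the signal strength in [0, 1], gamma_c is a small
cultivar intercept, and s_t is scaled so the treatment SD matches the
configured value.  Yields are truncated below at 0.1 t·ha⁻¹ (rarely
active at defaults).  Band reflectances couple to the *full* vigor
signal z_i = a·(shift_t + u_i): NIR increases and red decreases with
z_i, so the NDVI family of indices carries yield signal at strength
``a``, while blue, green and red-edge are independent noise.  Routing
the signal through bands (not directly through indices) makes the
correlated index families of real canopies arise naturally.

The band model is a phenomenological stand-in for real canopy optics —
no radiative transfer — and outputs are labelled synthetic.  One global
seed drives a per-plot counter-based substream, so record order never
changes results.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_sets import FeatureSubset
from .vegindex import list_indices

__all__ = [
    "SimConfig",
    "SyntheticTrial",
    "simulate_experiment",
    "planted_truth",
    "recovery_rate",
]

_BAND_BASE = {"blue": 0.06, "green": 0.12, "red": 0.10, "red_edge": 0.28, "nir": 0.45}
_NIR_GAIN = 0.06  # reflectance units per unit vigor
_RED_GAIN = 0.03


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Design and statistical structure of the simulated trial."""

    treatments: tuple[str, ...] = ("W1", "W2", "W3", "W4")
    yield_means: tuple[float, ...] = (7.77, 8.32, 8.97, 8.19)  # t/ha
    yield_sds: tuple[float, ...] = (1.56, 1.39, 1.19, 1.26)  # t/ha
    n_cultivars: int = 10
    n_reps: int = 3
    planted_indices: tuple[str, ...] = ("NDVI", "SAVI", "OSAVI")
    signal_strength: float = 0.9
    band_noise_sd: float = 0.02
    cultivar_sd: float = 0.3  # t/ha
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.treatments)
        if not (len(self.yield_means) == len(self.yield_sds) == k):
            raise ValueError("treatments, yield_means and yield_sds must align")
        if any(m <= 0 for m in self.yield_means) or any(s <= 0 for s in self.yield_sds):
            raise ValueError("yield means and SDs must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_cultivars < 1 or self.n_reps < 1:
            raise ValueError("need at least one cultivar and one replication")
        unknown = set(self.planted_indices) - set(list_indices())
        if unknown:
            raise ValueError(f"unknown planted index names: {sorted(unknown)}")

    @property
    def plots_per_treatment(self) -> int:
        return self.n_cultivars * self.n_reps

    @property
    def n_plots(self) -> int:
        return len(self.treatments) * self.plots_per_treatment

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticTrial:
    """A simulated trial: the plot table plus its ground truth."""

    plots: pd.DataFrame  # plot_id, treatment, cultivar, rep, 5 bands, yield_t_ha
    truth: dict  # latent vigor per plot, planted names, config echo
    config: SimConfig

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.plots.to_csv(outdir / "plots.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def simulate_experiment(config: SimConfig | None = None) -> SyntheticTrial:
    """Generate one synthetic trial; bit-identical for equal configs."""
    cfg = config or SimConfig()
    a = cfg.signal_strength
    grand_mean = float(np.mean(cfg.yield_means))
    sd_scale = float(np.mean(cfg.yield_sds))

    cult_rng = np.random.default_rng([cfg.seed, 999_983])
    cultivar_fx = cult_rng.normal(0.0, cfg.cultivar_sd, cfg.n_cultivars)

    rows = []
    latent = {}
    plot_counter = 0
    for t_idx, treatment in enumerate(cfg.treatments):
        mu_t = cfg.yield_means[t_idx]
        # treatment SD budget left for the within-treatment draw after the
        # cultivar intercepts claim their share
        s_t = float(np.sqrt(max(cfg.yield_sds[t_idx] ** 2 - cfg.cultivar_sd**2, 0.01)))
        shift_t = (mu_t - grand_mean) / sd_scale
        for cultivar in range(cfg.n_cultivars):
            for rep in range(cfg.n_reps):
                rng = np.random.default_rng([cfg.seed, plot_counter])
                u = rng.normal()
                e = rng.normal()
                z = a * (shift_t + u)  # vigor signal reaching the sensor
                y = mu_t + cultivar_fx[cultivar] + s_t * (a * u + np.sqrt(1 - a * a) * e)
                y = max(y, 0.1)
                noise = rng.normal(0.0, cfg.band_noise_sd, 5)
                bands = {
                    "blue": _BAND_BASE["blue"] + noise[0],
                    "green": _BAND_BASE["green"] + noise[1],
                    "red": _BAND_BASE["red"] - _RED_GAIN * z + noise[2],
                    "red_edge": _BAND_BASE["red_edge"] + noise[3],
                    "nir": _BAND_BASE["nir"] + _NIR_GAIN * z + noise[4],
                }
                bands = {k: float(np.clip(v, 0.001, 0.999)) for k, v in bands.items()}
                plot_id = f"P{plot_counter + 1:03d}"
                rows.append(
                    {
                        "plot_id": plot_id,
                        "treatment": treatment,
                        "cultivar": f"C{cultivar + 1:02d}",
                        "rep": rep + 1,
                        **bands,
                        "yield_t_ha": float(y),
                    }
                )
                latent[plot_id] = float(z)
                plot_counter += 1
    plots = pd.DataFrame(rows)
    truth = {
        "note": "synthetic trial (phenomenological band model, not real canopy optics)",
        "latent_vigor": latent,
        "planted_indices": list(cfg.planted_indices),
        "signal_strength": cfg.signal_strength,
        "config": cfg.to_dict(),
    }
    return SyntheticTrial(plots=plots, truth=truth, config=cfg)


def planted_truth(trial: SyntheticTrial) -> FeatureSubset:
    """The configured informative index names, for recovery scoring."""
    names = trial.truth["planted_indices"]
    if not names:
        return FeatureSubset(names=(), provenance=({"step": "planted_truth"},))
    return FeatureSubset.create(names, [{"step": "planted_truth"}])


def planted_only_vitable(trial: SyntheticTrial, dialect: str = "as_printed", seed: int | None = None):
    """Index table in which *only* the planted indices carry yield signal.

    Computes the full 35-index table from the trial's bands, then
    decouples every non-planted column from yield by a seeded
    within-column permutation.  Marginal distributions are preserved;
    the association with yield (and with the planted block) is
    destroyed.  This is the reference condition for selector-recovery
    scoring: because all 35 indices share five bands, a band-mediated
    trial alone cannot make exactly three indices informative — every
    NIR- or red-based index inherits part of the vigor signal.

    Returns a :class:`~yieldvi.vegindex.VITable`.
    """
    from .vegindex import VITable, compute_all

    vit = compute_all(trial.plots, dialect=dialect)
    planted = set(trial.truth["planted_indices"])
    rng_seed = trial.config.seed if seed is None else seed
    data = vit.data.copy()
    for j, col in enumerate(data.columns):
        if col in planted:
            continue
        rng = np.random.default_rng([rng_seed, 777_001, j])
        data[col] = rng.permutation(data[col].to_numpy())
    return VITable(data=data, dialect=dialect)


def recovery_rate(selected: Sequence[str] | FeatureSubset, planted: Sequence[str] | FeatureSubset) -> float:
    """|selected ∩ planted| / |planted| for any selector output."""
    sel = set(selected.names if isinstance(selected, FeatureSubset) else selected)
    pla = set(planted.names if isinstance(planted, FeatureSubset) else planted)
    if not pla:
        raise ValueError("planted set is empty; recovery rate undefined")
    return len(sel & pla) / len(pla)
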