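"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators emulate the study design of a mixed-ploidy duckweed
metabolomics experiment:

* :func:`simulate_feature_table` — log-normal feature intensities with
  additive strain, ploidy and strain x ploidy effects on the log2 scale,
  plus a configurable fraction of structurally ploidy-specific features
  (exactly zero in one cytotype of one strain, positive in the paired one).
* :func:`simulate_flow_observations` — gated nucleus counts drawn forward
  from the logit-normal cell-density model: the log-odds of a nucleus
  falling in the 4C peak is Normal(ln(rcd*rmass + odds(pG2)), theta), and a
  binomial count layer on top yields realistic integer counts.
* :func:`simulate_mass_observations` — dry mass as a zero-intercept line
  through fresh mass, dm = f_dry*m + noise, truncated to (0, m).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import FeatureTable, FlowObservation, MassObservation

DEFAULT_STRAINS = ("0013", "9242", "9316", "9346")


def _default_rcd() -> dict:
    # diploids have nearly twice the cells per fresh mass of tetraploids
    return {"0013": 0.52, "9242": 0.58, "9316": 0.62, "9346": 0.68}


def _default_pg2() -> dict:
    return {"0013": 0.03, "9242": 0.05, "9316": 0.06, "9346": 0.08}


def _default_fdry() -> dict:
    # WGD lowers the dry:fresh fraction, rf_dry ~ 0.85
    out = {}
    for strain, base in zip(DEFAULT_STRAINS, (0.048, 0.050, 0.052, 0.054)):
        out[(strain, "2n")] = base
        out[(strain, "4n")] = round(base * 0.85, 5)
    return out


@dataclass
class SimulationConfig:
    """Generative truth and design sizes for the synthetic study.

    Defaults mirror the study design: four strains, eight replicates per
    strain x cytotype, eight mixed-ploidy plus five pure-diploid flow
    samples, and twelve fresh/dry mass pairs per strain x cytotype with
    fresh masses spanning 28-909 mg.
    """

    seed: int = 0
    strains: tuple = DEFAULT_STRAINS
    n_replicates: int = 8
    n_features: int = 2000
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    strain_effect_sd: float = 1.0
    ploidy_effect_sd: float = 0.5
    interaction_effect_sd: float = 0.25
    noise_sd: float = 0.5
    frac_ploidy_specific: float = 0.01
    true_rcd: dict = field(default_factory=_default_rcd)
    true_pG2: dict = field(default_factory=_default_pg2)
    true_theta: float = 0.05
    nuclei_per_sample: int = 5000
    n_mixed_flow: int = 8
    n_diploid_flow: int = 5
    true_f_dry: dict = field(default_factory=_default_fdry)
    mass_noise_sd: float = 0.5
    n_mass_samples: int = 12
    fresh_mass_range: tuple = (28.0, 909.0)
    n_qc: int = 0

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def __post_init__(self) -> None:
        sds = {
            "baseline_log2_sd": self.baseline_log2_sd,
            "strain_effect_sd": self.strain_effect_sd,
            "ploidy_effect_sd": self.ploidy_effect_sd,
            "interaction_effect_sd": self.interaction_effect_sd,
            "noise_sd": self.noise_sd,
            "true_theta": self.true_theta,
            "mass_noise_sd": self.mass_noise_sd,
        }
        for name, value in sds.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if not np.isfinite(self.baseline_log2_mean):
            raise ValueError("baseline_log2_mean must be finite")
        if not 0 <= self.frac_ploidy_specific <= 1:
            raise ValueError("frac_ploidy_specific must be in [0, 1]")
        for strain in self.strains:
            rcd = self.true_rcd[strain]
            pg2 = self.true_pG2[strain]
            if not (np.isfinite(rcd) and rcd > 0):
                raise ValueError(f"true_rcd[{strain!r}] must be positive")
            if not 0 < pg2 < 1:
                raise ValueError(f"true_pG2[{strain!r}] must be in (0, 1)")
        for key, f in self.true_f_dry.items():
            if not 0 < f < 1:
                raise ValueError(f"true_f_dry[{key!r}] must be in (0, 1)")
        for count in (self.n_replicates, self.n_features, self.nuclei_per_sample):
            if count < 1:
                raise ValueError("counts must be >= 1")
        lo, hi = self.fresh_mass_range
        if not 0 < lo <= hi:
            raise ValueError("fresh_mass_range must satisfy 0 < low <= high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strains"] = list(self.strains)
        d["fresh_mass_range"] = list(self.fresh_mass_range)
        d["true_f_dry"] = {f"{s}:{p}": v for (s, p), v in self.true_f_dry.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["strains"] = tuple(d.get("strains", DEFAULT_STRAINS))
        if "fresh_mass_range" in d:
            d["fresh_mass_range"] = tuple(d["fresh_mass_range"])
        if "true_f_dry" in d and d["true_f_dry"] and isinstance(
            next(iter(d["true_f_dry"])), str
        ):
            d["true_f_dry"] = {
                tuple(k.split(":")): v for k, v in d["true_f_dry"].items()
            }
        return cls(**d)


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    """Independent substream keyed on the config seed plus a stage label."""
    words = [int(config.seed)]
    for item in stream:
        words.append(zlib.crc32(str(item).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(words)


def simulate_feature_table(
    config: SimulationConfig, platform: str = "ESI-"
) -> FeatureTable:
    """Draw one platform's samples x features intensity table.

    Raw-scale abundance is ``2**(baseline_f + strain_{f,s} + ploidy_{f,p} +
    interaction_{f,s,p} + eps)`` with ``eps ~ Normal(0, noise_sd)``; the 2n
    cytotype carries the zero level of the ploidy and interaction effects, so
    a feature's drawn ploidy effect IS its expected log2(4n/2n) group-mean
    difference.  A fraction ``frac_ploidy_specific`` of features is then
    zeroed out in all replicates of one randomly chosen strain x cytotype.

    The drawn effect vectors are kept in ``table.attrs["truth"]`` so tests
    can check realized moments against the generative ones.
    """
    rng = _rng(config, "features", platform)
    n_f = config.n_features
    strains = list(config.strains)
    n_s = len(strains)
    reps = config.n_replicates

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_f)
    strain_eff = rng.normal(0.0, config.strain_effect_sd, (n_s, n_f))
    ploidy_eff = rng.normal(0.0, config.ploidy_effect_sd, n_f)
    inter_eff = rng.normal(0.0, config.interaction_effect_sd, (n_s, n_f))

    rows, meta_rows = [], []
    for si, strain in enumerate(strains):
        for ploidy in ("2n", "4n"):
            dose = 1.0 if ploidy == "4n" else 0.0
            mean_log2 = (
                baseline + strain_eff[si] + dose * (ploidy_eff + inter_eff[si])
            )
            for rep in range(1, reps + 1):
                eps = rng.normal(0.0, config.noise_sd, n_f)
                rows.append(np.exp2(mean_log2 + eps))
                meta_rows.append(
                    {
                        "sample_id": f"{strain}_{ploidy}_r{rep}",
                        "strain": strain,
                        "ploidy": ploidy,
                        "replicate": rep,
                        "is_qc": False,
                    }
                )

    data = np.vstack(rows)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # structural ploidy-specific features: exact zeros in one cytotype of one
    # strain, strictly positive (guaranteed by 2**x > 0) in the paired one
    n_specific = int(round(config.frac_ploidy_specific * n_f))
    specific_idx = (
        rng.choice(n_f, size=n_specific, replace=False) if n_specific else np.array([], int)
    )
    specific_assign = {}
    for j in specific_idx:
        strain = strains[rng.integers(n_s)]
        absent_ploidy = "4n" if rng.random() < 0.5 else "2n"
        mask = (meta["strain"] == strain) & (meta["ploidy"] == absent_ploidy)
        data[mask.to_numpy(), j] = 0.0
        specific_assign[j] = (strain, absent_ploidy)

    if config.n_qc:
        qc_rows = []
        pooled = data.mean(axis=0)
        for q in range(1, config.n_qc + 1):
            eps = rng.normal(0.0, config.noise_sd, n_f)
            qc_rows.append(pooled * np.exp2(eps))
            meta.loc[f"QC_r{q}"] = {
                "strain": "QC", "ploidy": "QC", "replicate": q, "is_qc": True,
            }
        data = np.vstack([data, np.vstack(qc_rows)])

    feature_ids = [f"F{j:05d}" for j in range(n_f)]
    frame = pd.DataFrame(data, index=meta.index, columns=feature_ids)
    truth = {
        "baseline": baseline,
        "strain_effects": strain_eff,
        "ploidy_effects": ploidy_eff,
        "interaction_effects": inter_eff,
        "ploidy_specific": {feature_ids[j]: v for j, v in specific_assign.items()},
    }
    return FeatureTable(
        frame, meta, platform, attrs={"seed": config.seed, "truth": truth}
    )


def default_flow_design(config: SimulationConfig) -> list:
    """(strain, rmass) rows: mixed-ploidy samples with recorded fresh-mass
    ratios around parity, plus pure-diploid samples (rmass = 0)."""
    rng = _rng(config, "flow-design")
    design = []
    for strain in config.strains:
        for _ in range(config.n_mixed_flow):
            design.append((strain, float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))))
        for _ in range(config.n_diploid_flow):
            design.append((strain, 0.0))
    return design


def simulate_flow_observations(
    config: SimulationConfig, design: list | None = None
) -> list:
    """Draw gated nucleus counts for each (strain, rmass) design row.

    logit(p) ~ Normal(ln(rcd*rmass + pG2/(1 - pG2)), theta), then
    count_4C ~ Binomial(nuclei_per_sample, p).
    """
    if design is None:
        design = default_flow_design(config)
    rng = _rng(config, "flow")
    out = []
    for strain, rmass in design:
        if rmass < 0:
            raise ValueError(f"rmass must be >= 0, got {rmass}")
        pg2 = config.true_pG2[strain]
        odds = config.true_rcd[strain] * rmass + pg2 / (1.0 - pg2)
        mu = np.log(odds)
        lp = rng.normal(mu, config.true_theta) if config.true_theta > 0 else mu
        p = expit(lp)
        k4 = int(rng.binomial(config.nuclei_per_sample, p))
        out.append(
            FlowObservation(
                strain=strain,
                rmass=float(rmass),
                count_2C=config.nuclei_per_sample - k4,
                count_4C=k4,
            )
        )
    return out


def default_fresh_masses(config: SimulationConfig, strain: str, ploidy: str) -> list:
    """Log-uniform fresh masses (mg) over the configured sampling range."""
    rng = _rng(config, "mass-design", strain, ploidy)
    lo, hi = config.fresh_mass_range
    return list(np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_mass_samples)))


def simulate_mass_observations(
    config: SimulationConfig,
    fresh_masses: list,
    strain: str,
    ploidy: str,
) -> list:
    """Dry mass = f_dry * fresh mass + Normal noise, resampled into (0, m)."""
    if len(fresh_masses) == 0:
        raise ValueError("fresh_masses must be non-empty")
    if any(m <= 0 for m in fresh_masses):
        raise ValueError("fresh masses must be positive")
    rng = _rng(config, "mass", strain, ploidy)
    f_dry = config.true_f_dry[(strain, ploidy)]
    out = []
    for m in fresh_masses:
        dm = f_dry * m + rng.normal(0.0, config.mass_noise_sd)
        while not (0.0 < dm < m):
            dm = f_dry * m + rng.normal(0.0, config.mass_noise_sd)
        out.append(MassObservation(strain=strain, ploidy=ploidy, m=float(m), dm=float(dm)))
    return out


def simulate_all_mass_observations(config: SimulationConfig) -> list:
    """All strain x cytotype gravimetric series under the default design."""
    out = []
    for strain in config.strains:
        for ploidy in ("2n", "4n"):
            masses = default_fresh_masses(config, strain, ploidy)
            out.extend(simulate_mass_observations(config, masses, strain, ploidy))
    return out
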