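"""Relative cell density and per-cell fold-change normalization.

Whole-genome duplication enlarges cells, so tetraploid tissue packs fewer
cells per unit biomass than diploid tissue.  A tetraploid:diploid metabolite
fold change measured per dry mass (FCdm) therefore understates the per-cell
dosage response.  Two Bayesian models recover the conversion factor:

Model 1 (:class:`CellDensityModel`) — mixed-ploidy flow cytometry.  For a
sample mixing tetraploid and diploid tissue at fresh-mass ratio ``rmass``,
the log-odds of a nucleus falling in the 4C peak is

    logit(p4n) ~ Normal( ln(rcd * rmass + pG2/(1 - pG2)), theta )

whose slope ``rcd`` is the tetraploid:diploid cell density per fresh mass
and whose intercept is the odds of diploid G2/endoreduplicated nuclei
(``pG2``), pinned by pure-diploid samples (rmass = 0).

Model 2 (:class:`DryMassModel`) — zero-intercept regression of dry on fresh
mass, ``dm ~ Normal(f_dry * m, sigma)``, per strain x cytotype; the ratio
``rf_dry = f_dry,4n / f_dry,2n`` converts fresh-mass to dry-mass density:
``rcd_dm = rcd / rf_dry``.

Per-cell fold changes follow as ``FCcell = FCdm / mean(rcd_dm draws)`` and
are classified against full dosage compensation (FCcell = 1) and a 1:1
dosage effect (FCcell = 2).

Both models are fitted with the adaptive Metropolis engine in
:mod:`dosagefold.mcmc` (two chains, 2,000 iterations, 1,000 warmup by
default) under weakly regularizing priors, and report split R-hat and
effective sample size per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .containers import FeatureTable, FlowObservation, MassObservation
from .mcmc import SamplerSettings, diagnostics, run_chains

RHAT_SOFT_LIMIT = 1.05


# ---------------------------------------------------------------------------
# closed forms


def predict_p4n(rcd: float, pG2: float, rmass: float) -> float:
    """Expected 4C-peak proportion of a mixed sample.

    odds(p) = rcd * rmass + odds(pG2); at rmass = 0 this reduces to pG2.
    """
    if rcd <= 0:
        raise ValueError("rcd must be positive")
    if not 0 <= pG2 < 1:
        raise ValueError("pG2 must be in [0, 1)")
    if rmass < 0:
        raise ValueError("rmass must be >= 0")
    odds = rcd * rmass + pG2 / (1.0 - pG2)
    if odds == 0:
        warnings.warn("odds = 0: p4n is 0 in the limit", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(odds / (1.0 + odds))


def _as_param_maps(params, strains):
    """Normalise (rcd, pG2, theta) given as scalars or per-strain dicts."""
    rcd, pg2, theta = params
    if np.isscalar(rcd):
        rcd = {s: rcd for s in strains}
    if np.isscalar(pg2):
        pg2 = {s: pg2 for s in strains}
    return rcd, pg2, float(theta)


def model1_loglik(params, observations: list) -> float:
    """Log-likelihood of flow observations under the logit-normal model.

    ``params`` is ``(rcd, pG2, theta)`` with rcd/pG2 scalars or per-strain
    maps.  Observed proportions are continuity corrected,
    p_hat = (count_4C + 0.5)/(total + 1).  Non-finite or out-of-domain
    parameters give ``-inf``.
    """
    strains = sorted({o.strain for o in observations})
    rcd, pg2, theta = _as_param_maps(params, strains)
    vals = list(rcd.values()) + list(pg2.values()) + [theta]
    if not all(np.isfinite(v) for v in vals):
        return -np.inf
    if theta <= 0 or any(v <= 0 for v in rcd.values()):
        return -np.inf
    if any(not 0 < v < 1 for v in pg2.values()):
        return -np.inf
    total = 0.0
    for o in observations:
        odds = rcd[o.strain] * o.rmass + pg2[o.strain] / (1.0 - pg2[o.strain])
        mu = np.log(odds)
        total += stats.norm.logpdf(logit(o.p4n_hat), mu, theta)
    return float(total)


# ---------------------------------------------------------------------------
# priors


@dataclass
class CellDensityPriors:
    """Weakly regularizing priors for Model 1 (all exposed)."""

    rcd_mean: float = 1.0
    rcd_sd: float = 1.0  # Normal truncated to rcd > 0
    pg2_a: float = 1.5
    pg2_b: float = 10.0  # Beta
    theta_scale: float = 1.0  # HalfNormal

    def logpdf(self, rcd: np.ndarray, pg2: np.ndarray, theta) -> float:
        lp = -0.5 * np.sum(((rcd - self.rcd_mean) / self.rcd_sd) ** 2)
        lp += np.sum(stats.beta.logpdf(pg2, self.pg2_a, self.pg2_b))
        lp += -0.5 * np.sum((np.asarray(theta) / self.theta_scale) ** 2)
        return float(lp)


@dataclass
class DryMassPriors:
    """f_dry ~ Uniform(0, 1); residual sd ~ HalfNormal(sigma_scale) [mg]."""

    sigma_scale: float = 10.0

    def logpdf(self, f_dry: float, sigma: float) -> float:
        return float(-0.5 * (sigma / self.sigma_scale) ** 2)


# ---------------------------------------------------------------------------
# Model 1: relative cell density from mixed-ploidy flow cytometry


class CellDensityModel:
    """Joint logit-normal model of 4C-peak proportions across strains.

    Strains share the residual scale ``theta`` (set ``share_theta=False``
    for a per-strain scale) and carry strain-indexed ``rcd`` and ``pG2``.

    Parameters
    ----------
    observations
        :class:`~dosagefold.containers.FlowObservation` records; every strain
        should include both mixed (rmass > 0) and pure-diploid (rmass = 0)
        samples — without the latter pG2 is weakly identified (warning).
    priors
        :class:`CellDensityPriors`; defaults are weakly regularizing.
    """

    def __init__(
        self,
        observations: list,
        priors: CellDensityPriors | None = None,
        share_theta: bool = True,
    ):
        if not observations:
            raise ValueError("no observations")
        self.observations = list(observations)
        self.priors = priors or CellDensityPriors()
        self.share_theta = share_theta
        self.strains = sorted({o.strain for o in observations})
        for s in self.strains:
            obs_s = [o for o in observations if o.strain == s]
            if not any(o.rmass == 0 for o in obs_s):
                warnings.warn(
                    f"strain {s!r} has no pure-diploid (rmass = 0) samples; "
                    "pG2 is weakly identified",
                    UserWarning,
                    stacklevel=2,
                )
            if not any(o.rmass > 0 for o in obs_s):
                warnings.warn(
                    f"strain {s!r} has no mixed (rmass > 0) samples; "
                    "rcd is weakly identified",
                    UserWarning,
                    stacklevel=2,
                )
        self._sidx = np.array([self.strains.index(o.strain) for o in observations])
        self._rmass = np.array([o.rmass for o in observations])
        self._y = logit(np.array([o.p4n_hat for o in observations]))
        self._n_s = len(self.strains)
        self._n_theta = 1 if share_theta else self._n_s
        self.n_params = 2 * self._n_s + self._n_theta

    # unconstrained vector: [log rcd_s ..., logit pG2_s ..., log theta(s)]
    def _unpack(self, x: np.ndarray):
        k = self._n_s
        rcd = np.exp(x[:k])
        pg2 = expit(x[k : 2 * k])
        theta = np.exp(x[2 * k :])
        return rcd, pg2, theta

    def log_post(self, x: np.ndarray) -> float:
        rcd, pg2, theta = self._unpack(x)
        if not (np.all(np.isfinite(rcd)) and np.all(np.isfinite(theta))):
            return -np.inf
        if np.any(pg2 <= 0) or np.any(pg2 >= 1):
            return -np.inf
        odds = rcd[self._sidx] * self._rmass + pg2[self._sidx] / (1 - pg2[self._sidx])
        mu = np.log(odds)
        th = theta[0] if self.share_theta else theta[self._sidx]
        resid = self._y - mu
        loglik = float(np.sum(-0.5 * (resid / th) ** 2 - np.log(th)))
        lp = self.priors.logpdf(rcd, pg2, theta)
        # Jacobians of log/logit transforms
        jac = np.sum(np.log(rcd)) + np.sum(np.log(pg2 * (1 - pg2))) + np.sum(np.log(theta))
        return float(loglik + lp + jac)

    def _initial_point(self) -> np.ndarray:
        pg2_init, rcd_init = [], []
        for i, s in enumerate(self.strains):
            dip = [o.p4n_hat for o in self.observations if o.strain == s and o.rmass == 0]
            pg2 = float(np.clip(np.mean(dip) if dip else 0.05, 1e-4, 0.5))
            pg2_init.append(pg2)
            mixed = [
                (o.p4n_hat, o.rmass)
                for o in self.observations
                if o.strain == s and o.rmass > 0
            ]
            if mixed:
                ests = [
                    max((p / (1 - p) - pg2 / (1 - pg2)) / r, 1e-3) for p, r in mixed
                ]
                rcd_init.append(float(np.median(ests)))
            else:
                rcd_init.append(1.0)
        x0 = np.concatenate(
            [
                np.log(rcd_init),
                logit(np.array(pg2_init)),
                np.full(self._n_theta, np.log(0.1)),
            ]
        )
        return x0

    def fit(
        self,
        chains: int = 2,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int | None = None,
    ) -> "CellDensityResults":
        """Run the adaptive Metropolis sampler and wrap the posterior."""
        settings = SamplerSettings(chains=chains, iterations=iterations, warmup=warmup)
        rng = np.random.default_rng(seed)
        draws = run_chains(self.log_post, self._initial_point(), settings, rng)
        return CellDensityResults(self, draws, settings)


class CellDensityResults:
    """Posterior draws of rcd, pG2 and theta with convergence diagnostics."""

    def __init__(self, model: CellDensityModel, draws: np.ndarray, settings):
        self.model = model
        self.settings = settings
        self._raw = draws  # chains x kept x dim, unconstrained
        k = model._n_s
        self.posterior: dict[str, np.ndarray] = {}
        for i, s in enumerate(model.strains):
            self.posterior[f"rcd[{s}]"] = np.exp(draws[:, :, i])
            self.posterior[f"pG2[{s}]"] = expit(draws[:, :, k + i])
        if model.share_theta:
            self.posterior["theta"] = np.exp(draws[:, :, 2 * k])
        else:
            for i, s in enumerate(model.strains):
                self.posterior[f"theta[{s}]"] = np.exp(draws[:, :, 2 * k + i])
        self.diagnostics = diagnostics(self.posterior)
        bad = {
            p: d["rhat"] for p, d in self.diagnostics.items()
            if d["rhat"] > RHAT_SOFT_LIMIT
        }
        if bad:
            warnings.warn(
                f"split R-hat above {RHAT_SOFT_LIMIT} for {sorted(bad)}; "
                "inspect chain mixing",
                UserWarning,
                stacklevel=2,
            )

    @property
    def strains(self) -> list:
        return self.model.strains

    def rcd_draws(self, strain: str) -> np.ndarray:
        return self.posterior[f"rcd[{strain}]"].ravel()

    def pg2_draws(self, strain: str) -> np.ndarray:
        return self.posterior[f"pG2[{strain}]"].ravel()

    def rcd_mean(self, strain: str) -> float:
        return float(self.rcd_draws(strain).mean())

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, central 90% interval, R-hat and ESS."""
        rows = []
        for name, arr in self.posterior.items():
            flat = arr.ravel()
            lo, hi = np.percentile(flat, [5, 95])
            d = self.diagnostics[name]
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q5": lo,
                    "q95": hi,
                    "rhat": d["rhat"],
                    "ess": d["ess"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


def fit_cell_density(
    observations: list, settings: SamplerSettings | None = None, seed: int | None = None,
    priors: CellDensityPriors | None = None,
) -> CellDensityResults:
    """Functional wrapper: build a :class:`CellDensityModel` and fit it."""
    settings = settings or SamplerSettings()
    model = CellDensityModel(observations, priors=priors)
    return model.fit(
        chains=settings.chains,
        iterations=settings.iterations,
        warmup=settings.warmup,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model 2: dry:fresh mass fraction


class DryMassModel:
    """Zero-intercept Bayesian regression dm ~ Normal(f_dry * m, sigma),
    fitted independently per strain x cytotype group."""

    def __init__(self, observations: list, priors: DryMassPriors | None = None):
        if not observations:
            raise ValueError("no observations")
        self.priors = priors or DryMassPriors()
        self.groups: dict[tuple, list] = {}
        for o in observations:
            self.groups.setdefault((o.strain, o.ploidy), []).append(o)
        for key, obs in self.groups.items():
            if len(obs) < 3:
                raise ValueError(f"group {key} needs >= 3 observations")
            if all(o.m == 0 for o in obs):
                raise ValueError(f"group {key} has no positive fresh mass")

    @staticmethod
    def closed_form_fdry(observations: list) -> float:
        """Flat-prior / least-squares slope through the origin,
        sum(dm*m)/sum(m^2)."""
        m = np.array([o.m for o in observations])
        dm = np.array([o.dm for o in observations])
        return float(np.sum(dm * m) / np.sum(m**2))

    def _log_post_factory(self, obs: list):
        m = np.array([o.m for o in obs])
        dm = np.array([o.dm for o in obs])
        priors = self.priors

        def log_post(x: np.ndarray) -> float:
            f_dry = expit(x[0])
            sigma = np.exp(x[1])
            if not np.isfinite(sigma) or sigma <= 0:
                return -np.inf
            resid = dm - f_dry * m
            loglik = np.sum(-0.5 * (resid / sigma) ** 2 - np.log(sigma))
            lp = priors.logpdf(f_dry, sigma)
            jac = np.log(f_dry * (1 - f_dry)) + np.log(sigma)
            return float(loglik + lp + jac)

        return log_post

    def fit(
        self,
        chains: int = 2,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int | None = None,
    ) -> "DryMassResults":
        settings = SamplerSettings(chains=chains, iterations=iterations, warmup=warmup)
        rng = np.random.default_rng(seed)
        posterior = {}
        for key in sorted(self.groups):
            obs = self.groups[key]
            slope = np.clip(self.closed_form_fdry(obs), 1e-4, 1 - 1e-4)
            resid_sd = float(
                np.std([o.dm - slope * o.m for o in obs], ddof=1) or 1e-3
            )
            x0 = np.array([logit(slope), np.log(max(resid_sd, 1e-3))])
            draws = run_chains(self._log_post_factory(obs), x0, settings, rng)
            posterior[key] = {
                "f_dry": expit(draws[:, :, 0]),
                "sigma": np.exp(draws[:, :, 1]),
            }
        return DryMassResults(self, posterior, settings)


class DryMassResults:
    """Posterior of f_dry per strain x cytotype; derived rf_dry per strain."""

    def __init__(self, model: DryMassModel, posterior: dict, settings):
        self.model = model
        self.posterior = posterior
        self.settings = settings
        flat = {}
        for (s, p), d in posterior.items():
            flat[f"f_dry[{s},{p}]"] = d["f_dry"]
        self.diagnostics = diagnostics(flat)

    @property
    def strains(self) -> list:
        return sorted({s for s, _ in self.posterior})

    def f_dry_draws(self, strain: str, ploidy: str) -> np.ndarray:
        return self.posterior[(strain, ploidy)]["f_dry"].ravel()

    def f_dry_mean(self, strain: str, ploidy: str) -> float:
        return float(self.f_dry_draws(strain, ploidy).mean())

    def rf_dry_draws(self, strain: str) -> np.ndarray:
        """Tetraploid:diploid ratio of f_dry, paired across posterior draws."""
        f4 = self.f_dry_draws(strain, "4n")
        f2 = self.f_dry_draws(strain, "2n")
        return f4 / f2

    def summary(self) -> pd.DataFrame:
        rows = []
        for (s, p), d in sorted(self.posterior.items()):
            flat = d["f_dry"].ravel()
            diag = self.diagnostics[f"f_dry[{s},{p}]"]
            rows.append(
                {
                    "strain": s,
                    "ploidy": p,
                    "f_dry_mean": flat.mean(),
                    "f_dry_sd": flat.std(ddof=1),
                    "rhat": diag["rhat"],
                    "ess": diag["ess"],
                }
            )
        return pd.DataFrame(rows).set_index(["strain", "ploidy"])


def fit_dry_fraction(
    observations: list, settings: SamplerSettings | None = None, seed: int | None = None,
    priors: DryMassPriors | None = None,
) -> DryMassResults:
    """Functional wrapper: build a :class:`DryMassModel` and fit it."""
    settings = settings or SamplerSettings()
    model = DryMassModel(observations, priors=priors)
    return model.fit(
        chains=settings.chains,
        iterations=settings.iterations,
        warmup=settings.warmup,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# posterior combination and per-cell fold changes


def combine_rcd_dm(
    cell: CellDensityResults,
    mass: DryMassResults,
    n_draws: int = 500,
    paired: bool = False,
    seed: int | None = None,
) -> dict:
    """Per-strain rcd_dm = rcd / rf_dry draws from the two posteriors.

    Default combines every one of ``n_draws`` rcd draws with every one of
    ``n_draws`` rf_dry draws (n_draws**2 ratios); ``paired=True`` pairs them
    one-to-one instead (same mean in expectation, fewer values).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for strain in cell.strains:
        rcd = cell.rcd_draws(strain)
        rf = mass.rf_dry_draws(strain)
        if len(rcd) < n_draws or len(rf) < n_draws:
            raise ValueError(
                f"need >= {n_draws} post-warmup draws, have "
                f"{len(rcd)} rcd and {len(rf)} rf_dry"
            )
        rcd_sub = rng.choice(rcd, size=n_draws, replace=False)
        rf_sub = rng.choice(rf, size=n_draws, replace=False)
        if paired:
            out[strain] = rcd_sub / rf_sub
        else:
            out[strain] = np.outer(rcd_sub, 1.0 / rf_sub).ravel()
    return out


def pair_presence_filter(unfiltered_table: FeatureTable, strain: str) -> FeatureTable:
    """Features with positive abundance in every biological sample of the
    strain's diploid-tetraploid pair (raw, unfiltered table)."""
    bio = unfiltered_table.non_qc()
    sel = (bio.sample_meta["strain"] == strain).to_numpy()
    vals = np.nan_to_num(bio.data.loc[sel].to_numpy(dtype=float), nan=0.0)
    keep = np.all(vals > 0, axis=0)
    kept_ids = [f for f, k in zip(unfiltered_table.feature_ids, keep) if k]
    return unfiltered_table.select_features(kept_ids)


DOSAGE_LABELS = (
    "overcompensation",       # FCcell < 1
    "full_compensation",      # FCcell == 1 (boundary)
    "partial_compensation",   # 1 < FCcell < 2
    "one_to_one_dosage",      # FCcell == 2 (boundary)
    "positive_dosage_effect", # FCcell > 2
)


def classify_dosage(fccell: np.ndarray) -> tuple[np.ndarray, dict]:
    """Label per-cell fold changes against the dosage benchmarks.

    FCcell = 1 is full dosage compensation, FCcell = 2 a 1:1 dosage effect;
    values below 1 are overcompensation, values above 2 positive dosage
    effects.  Returns (labels, class proportions over the three regions,
    boundaries folded into the middle region).
    """
    fccell = np.asarray(fccell, dtype=float)
    if (fccell < 0).any():
        raise ValueError("FCcell must be >= 0")
    labels = np.select(
        [fccell < 1, fccell == 1, fccell < 2, fccell == 2],
        DOSAGE_LABELS[:4],
        default=DOSAGE_LABELS[4],
    )
    n = len(fccell)
    summary = {
        "overcompensation": float(np.mean(fccell < 1)) if n else 0.0,
        "partial_to_full_compensation": float(np.mean((fccell >= 1) & (fccell <= 2)))
        if n
        else 0.0,
        "positive_dosage_effect": float(np.mean(fccell > 2)) if n else 0.0,
    }
    return labels, summary


@dataclass
class FoldChangeResult:
    """Per-feature FCdm/FCcell with dosage classes and per-strain medians."""

    table: pd.DataFrame  # columns: strain, feature, lfc, FCdm, FCcell, dosage_class
    summary: pd.DataFrame  # index strain: median_FCdm, median_FCcell, mean_rcd_dm
    class_proportions: dict = field(default_factory=dict)


def fc_per_cell(lfc_by_strain, rcd_dm_by_strain) -> FoldChangeResult:
    """Convert per-dry-mass log2 fold changes to per-cell fold changes.

    ``FCdm = 2**lfc`` and ``FCcell = FCdm / mean(rcd_dm draws)`` per strain.
    Accepts either per-strain dicts (Series of lfc, array of rcd_dm draws)
    or a single Series + array (treated as one unnamed strain).
    """
    if not isinstance(lfc_by_strain, dict):
        lfc_by_strain = {"all": lfc_by_strain}
        rcd_dm_by_strain = {"all": rcd_dm_by_strain}
    rows, summaries, props = [], [], {}
    for strain, lfc in lfc_by_strain.items():
        lfc = pd.Series(lfc)
        if lfc.empty:
            raise ValueError(f"strain {strain!r}: empty feature set")
        draws = np.asarray(rcd_dm_by_strain[strain], dtype=float)
        mean_rcd_dm = float(draws.mean())
        fcdm = np.exp2(lfc.to_numpy(dtype=float))
        fccell = fcdm / mean_rcd_dm
        labels, prop = classify_dosage(fccell)
        props[strain] = prop
        rows.append(
            pd.DataFrame(
                {
                    "strain": strain,
                    "feature": lfc.index,
                    "lfc": lfc.to_numpy(dtype=float),
                    "FCdm": fcdm,
                    "FCcell": fccell,
                    "dosage_class": labels,
                }
            )
        )
        summaries.append(
            {
                "strain": strain,
                "median_FCdm": float(np.median(fcdm)),
                "median_FCcell": float(np.median(fccell)),
                "mean_rcd_dm": mean_rcd_dm,
            }
        )
    return FoldChangeResult(
        table=pd.concat(rows, ignore_index=True),
        summary=pd.DataFrame(summaries).set_index("strain"),
        class_proportions=props,
    )
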