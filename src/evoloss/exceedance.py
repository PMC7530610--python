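"""Simulation test for strains whose expected growth rate exceeds wild type.

The statistic is the sum, over every non-wild-type growth-rate observation,
of the positive part of its z-score against the wild-type mean and SD
(negative z-scores are set to zero).  The null distribution is obtained by
simulation: datasets matching the observed composition are drawn with every
strain at the wild-type Normal(mu_wt, sigma_wt), and the statistic is
recomputed.  A within-strain bootstrap of the observed statistic quantifies
how much it depends on individual observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExceedanceDesign",
    "ExceedanceResult",
    "positive_z_sum",
    "simulate_null",
    "exceedance_p",
    "bootstrap_statistic",
    "run_test",
    "subset_test",
    "read_rates_tsv",
    "write_result_json",
]


@dataclass(frozen=True)
class ExceedanceDesign:
    """Per-strain growth-rate observations plus the wild-type reference.

    ``mu_wt``/``sigma_wt`` default to the sample mean and SD (ddof=1) of the
    wild-type observations but may be given explicitly, in which case the
    wild-type observations are optional.
    """

    strains: dict[str, np.ndarray]
    wildtype: np.ndarray | None = None
    mu_wt: float = field(default=None)  # type: ignore[assignment]
    sigma_wt: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        strains = {
            k: np.asarray(v, dtype=float).ravel() for k, v in self.strains.items()
        }
        object.__setattr__(self, "strains", strains)
        if not strains:
            raise ValueError("design has no strains")
        for name, obs in strains.items():
            if obs.size < 1:
                raise ValueError(f"strain {name!r} has no observations")
        if self.mu_wt is None or self.sigma_wt is None:
            if self.wildtype is None:
                raise ValueError(
                    "either wild-type observations or (mu_wt, sigma_wt) required"
                )
            wt = np.asarray(self.wildtype, dtype=float).ravel()
            if wt.size < 2:
                raise ValueError("need >= 2 wild-type observations for mean and SD")
            object.__setattr__(self, "wildtype", wt)
            object.__setattr__(self, "mu_wt", float(wt.mean()))
            object.__setattr__(self, "sigma_wt", float(wt.std(ddof=1)))
        if not self.sigma_wt > 0:
            raise ValueError("sigma_wt must be > 0")

    @property
    def n_observations(self) -> int:
        return sum(v.size for v in self.strains.values())

    def subset(self, predicate) -> "ExceedanceDesign":
        kept = {k: v for k, v in self.strains.items() if predicate(k)}
        if not kept:
            raise ValueError("predicate selects no strains")
        return ExceedanceDesign(
            strains=kept,
            wildtype=self.wildtype,
            mu_wt=self.mu_wt,
            sigma_wt=self.sigma_wt,
        )


@dataclass(frozen=True)
class ExceedanceResult:
    statistic: float
    p_value: float
    n_null_reps: int
    bootstrap_percentiles: dict[str, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def _positive_z(design: ExceedanceDesign, collapse: str) -> np.ndarray:
    """Clamped z-score of every data point (or of per-strain means)."""
    if collapse == "observations":
        vals = np.concatenate(list(design.strains.values()))
    elif collapse == "strain_means":
        vals = np.array([v.mean() for v in design.strains.values()])
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    z = (vals - design.mu_wt) / design.sigma_wt
    return np.maximum(z, 0.0)


def positive_z_sum(design: ExceedanceDesign, collapse: str = "observations") -> float:
    """S = sum over data points of max(0, (x - mu_wt) / sigma_wt).

    Wild-type observations do not contribute (only the non-wild-type strains
    in the design are summed).  ``collapse="strain_means"`` computes one
    z-score per strain mean instead of per observation, a sensitivity mode
    for when replicates are not treated as independent data points.
    """
    return float(_positive_z(design, collapse).sum())


def simulate_null(
    design: ExceedanceDesign,
    n_reps: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    collapse: str = "observations",
) -> np.ndarray:
    """Null sample of S: composition-matched datasets, every strain at WT.

    Each replicate draws, for every strain, the same number of observations
    as observed, i.i.d. Normal(mu_wt, sigma_wt), and records the positive
    z-score sum.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = np.array([v.size for v in design.strains.values()])
    if collapse == "observations":
        z = rng.standard_normal((n_reps, int(sizes.sum())))
    elif collapse == "strain_means":
        # mean of n_i iid N(0,1) has sd 1/sqrt(n_i)
        z = rng.standard_normal((n_reps, sizes.size)) / np.sqrt(sizes)
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    return np.maximum(z, 0.0).sum(axis=1)


def exceedance_p(s_obs: float, null_sample: np.ndarray) -> float:
    """Add-one empirical p-value: (1 + #{S_null >= S_obs}) / (1 + n_reps)."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null_sample >= s_obs)) / (1 + null_sample.size))


def bootstrap_statistic(
    design: ExceedanceDesign,
    n_boot: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    collapse: str = "observations",
) -> np.ndarray:
    """Bootstrap distribution of S, resampling within each strain.

    Observations are resampled with replacement strain by strain so the
    composition of the design is preserved.  Used to judge how strongly the
    observed statistic depends on a handful of outliers.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if collapse == "observations":
        out = np.zeros(n_boot)
        for obs in design.strains.values():
            z = np.maximum((obs - design.mu_wt) / design.sigma_wt, 0.0)
            idx = rng.integers(0, obs.size, size=(n_boot, obs.size))
            out += z[idx].sum(axis=1)
        return out
    if collapse == "strain_means":
        out = np.zeros(n_boot)
        means = np.empty((n_boot, len(design.strains)))
        for j, obs in enumerate(design.strains.values()):
            idx = rng.integers(0, obs.size, size=(n_boot, obs.size))
            means[:, j] = obs[idx].mean(axis=1)
        z = np.maximum((means - design.mu_wt) / design.sigma_wt, 0.0)
        return z.sum(axis=1)
    raise ValueError(f"unknown collapse mode {collapse!r}")


_PCTL = (2.5, 25.0, 50.0, 75.0, 97.5)


def run_test(
    design: ExceedanceDesign,
    n_reps: int = 10_000,
    n_boot: int = 10_000,
    seed: int | None = None,
    collapse: str = "observations",
) -> ExceedanceResult:
    """Full exceedance test: statistic, simulated-null p, bootstrap summary."""
    rng = np.random.default_rng(seed)
    s_obs = positive_z_sum(design, collapse)
    null = simulate_null(design, n_reps=n_reps, rng=rng, collapse=collapse)
    p = exceedance_p(s_obs, null)
    boot = bootstrap_statistic(design, n_boot=n_boot, rng=rng, collapse=collapse)
    pctl = {f"p{q:g}": float(np.percentile(boot, q)) for q in _PCTL}
    return ExceedanceResult(
        statistic=s_obs,
        p_value=p,
        n_null_reps=n_reps,
        bootstrap_percentiles=pctl,
        seed=seed,
    )


def subset_test(
    design: ExceedanceDesign,
    predicate,
    n_reps: int = 10_000,
    n_boot: int = 10_000,
    seed: int | None = None,
    collapse: str = "observations",
) -> ExceedanceResult:
    """Run the full test on the strains selected by ``predicate``.

    Used e.g. to restrict to deletion strains whose initial growth rates are
    similar to the wild type.
    """
    return run_test(
        design.subset(predicate),
        n_reps=n_reps,
        n_boot=n_boot,
        seed=seed,
        collapse=collapse,
    )


# ---------------------------------------------------------------------------
# File interfaces


def read_rates_tsv(path) -> ExceedanceDesign:
    """TSV with columns strain, replicate, growth_rate, is_wild_type."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    wt_mask = df["is_wild_type"].astype(bool)
    strains = {
        str(name): grp["growth_rate"].to_numpy(float)
        for name, grp in df[~wt_mask].groupby("strain", sort=False)
    }
    return ExceedanceDesign(
        strains=strains, wildtype=df.loc[wt_mask, "growth_rate"].to_numpy(float)
    )


def write_result_json(result: ExceedanceResult, path) -> None:
    payload = {
        "statistic": result.statistic,
        "p_value": result.p_value,
        "n_null_reps": result.n_null_reps,
        "bootstrap_percentiles": result.bootstrap_percentiles,
        "seed": result.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
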