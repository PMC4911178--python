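"""Replicated parameter sweeps over the four clustering scenarios.

The four scenarios probe what drives nuclear clustering in the syncytium:

* ``adhesion``     — sweep the stickiness S of the internuclear well;
* ``diffusion``    — sweep the diffusion constant D while co-varying S to
  hold the dimensionless well depth S/D fixed (diffusion alone would
  otherwise also change the effective adhesiveness);
* ``fusion_sites`` — sweep the fusion-site spread sigma of the entry-position
  distribution Normal(L/2, sigma^2); run staged so entry position matters;
* ``amplitude``    — sweep the multiplier A on the boundary-thickness
  variation.

Each grid value is simulated with ``n_replicates`` independent seeds
(derived deterministically from a master seed) and summarised by the
mass-weighted mean cluster size per nucleus plus cluster-census counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import cluster_census, mean_cluster_size_per_nucleus
from .simulate import SimParams, run_simulation

__all__ = [
    "SCENARIOS",
    "DEFAULT_GRIDS",
    "SweepSpec",
    "SweepResult",
    "covary_adhesion_with_diffusion",
    "run_sweep",
]

SCENARIOS = ("adhesion", "diffusion", "fusion_sites", "amplitude")

# Default grids: S spans a decade around the base stickiness, D two decades
# either side of the base diffusion (with S co-varied) so both the
# collision-limited and the unsticking regime are covered, sigma from tightly
# focal fusion to uniform entry (inf).  A stops at 1: beyond the three-sigma
# design bound of the boundary the channel pinches below one nuclear
# diameter, which changes the domain topology rather than its thickness.
DEFAULT_GRIDS: Dict[str, Tuple[float, ...]] = {
    "adhesion": (0.2, 0.5, 1.0, 1.5, 2.0),
    "diffusion": (0.002, 0.02, 0.2, 2.0, 8.0),
    "fusion_sites": (2.5, 5.0, 10.0, 25.0, np.inf),
    "amplitude": (0.0, 0.25, 0.5, 1.0),
}


@dataclass(frozen=True)
class SweepSpec:
    """One scenario sweep: grid, replication and base parameters."""

    scenario: str
    parameter_values: Tuple[float, ...] = ()
    n_replicates: int = 50
    base_params: SimParams = field(default_factory=SimParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if not self.parameter_values:
            object.__setattr__(
                self, "parameter_values", DEFAULT_GRIDS[self.scenario]
            )


@dataclass
class SweepResult:
    """Per-replicate rows plus aggregation helpers."""

    spec: SweepSpec
    table: pd.DataFrame  # scenario, value, replicate, seed, metrics
    n_failures: int = 0

    def aggregate(self, metric: str = "mean_cluster_size_weighted") -> pd.DataFrame:
        """Mean and t-based 95% interval of a metric per grid value."""
        def _ci(x: pd.Series) -> Tuple[float, float]:
            m = x.mean()
            half = stats.t.ppf(0.975, len(x) - 1) * x.sem()
            return m - half, m + half

        grouped = self.table.groupby("value")[metric]
        out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
        ci = grouped.apply(_ci)
        out["ci_lo"] = [c[0] for c in ci]
        out["ci_hi"] = [c[1] for c in ci]
        return out


def covary_adhesion_with_diffusion(
    D_values: Sequence[float], base_S: float, base_D: float
) -> List[Tuple[float, float]]:
    """Paired (D, S) settings holding the well depth S/D constant.

    ``S(D) = base_S * D / base_D`` — for an overdamped particle the escape
    probability from the adhesive well is governed by S/D (D plays the role
    of temperature at unit mobility), so this keeps the effective
    adhesiveness unchanged while diffusion is swept.
    """
    if not base_D > 0:
        raise ValueError("base_D must be positive")
    pairs = []
    for D in D_values:
        if not D > 0:
            raise ValueError("diffusion grid values must be positive")
        pairs.append((float(D), base_S * float(D) / base_D))
    return pairs


def _params_for_value(spec: SweepSpec, value: float) -> SimParams:
    base = spec.base_params
    if spec.scenario == "adhesion":
        return base.with_(potential=replace(base.potential, adhesion_strength=value))
    if spec.scenario == "diffusion":
        (D, S), = covary_adhesion_with_diffusion(
            [value], base.potential.adhesion_strength, base.diffusion
        )
        return base.with_(
            diffusion=D, potential=replace(base.potential, adhesion_strength=S)
        )
    if spec.scenario == "fusion_sites":
        sigma = None if not np.isfinite(value) else value
        # entry position only matters while nuclei are still arriving
        return base.with_(fusion_site_sd=sigma, injection_mode="staged")
    if spec.scenario == "amplitude":
        return base.with_(boundary=replace(base.boundary, amplitude=value))
    raise AssertionError(spec.scenario)


def run_sweep(spec: SweepSpec, progress: Optional[callable] = None) -> SweepResult:
    """Run all (value, replicate) simulations and tabulate cluster metrics.

    Replicate seeds are spawned deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence``, so the whole sweep is reproducible.
    Individual replicate failures are recorded and the sweep continues.
    """
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(len(spec.parameter_values))
    rows = []
    failures = 0
    for vi, value in enumerate(spec.parameter_values):
        params_v = _params_for_value(spec, value)
        rep_seeds = children[vi].spawn(spec.n_replicates)
        for rep in range(spec.n_replicates):
            seed = int(rep_seeds[rep].generate_state(1)[0] % (2**31))
            try:
                result = run_simulation(params_v.with_(seed=seed))
            except Exception as exc:  # noqa: BLE001 - replicate failures are data
                failures += 1
                rows.append(
                    dict(scenario=spec.scenario, value=value, replicate=rep,
                         seed=seed, error=str(exc))
                )
                continue
            final = result.final_clusters()
            rows.append(
                dict(
                    scenario=spec.scenario,
                    value=value,
                    replicate=rep,
                    seed=seed,
                    mean_cluster_size_weighted=mean_cluster_size_per_nucleus(final),
                    mean_cluster_size_unweighted=final.mean_size,
                    n_clusters_ge2=cluster_census(final, 2),
                    n_clusters_gt6=cluster_census(final, 7),
                    error="",
                )
            )
            if progress is not None:
                progress(spec.scenario, value, rep)
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""].drop(columns="error").reset_index(drop=True)
    return SweepResult(spec, ok, n_failures=failures)
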