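"""Model/Results front end for module-stability analysis.

``ModuleStabilityModel`` holds the data matrix; ``fit`` runs the full
bootstrap stability pipeline over a threshold grid and returns a
``ModuleStabilityResults`` carrying the stability profile, the selected
threshold, the modules and the conditional stability report at the optimum,
with ``summary()`` and plotting attached.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .graph import pearson_correlation, read_data, threshold_graph, validate_data
from .modules import ModuleSet, fast_greedy_modules
from .selection import SIMULATION_GRID, StabilityProfile, stability_profile
from .stability import StabilityReport, bootstrap_modules, stability_report

__all__ = ["ModuleStabilityModel", "ModuleStabilityResults"]


class ModuleStabilityModel:
    """Bootstrap stability model for module detection in a correlation graph.

    Parameters
    ----------
    data : array-like or DataFrame, shape (N, p)
        Observations by variables.
    variable_names : sequence of str, optional
        Required when ``data`` is a bare array; ignored for DataFrames.

    Examples
    --------
    >>> model = ModuleStabilityModel.from_csv("metabolites.csv")
    >>> res = model.fit(B=100, m=50, seed=7)
    >>> res.t_opt, res.modules_.n_modules       # doctest: +SKIP
    """

    def __init__(self, data, variable_names=None):
        if isinstance(data, pd.DataFrame):
            df = data.copy()
        else:
            values = np.asarray(data, dtype=float)
            if variable_names is None:
                variable_names = [f"V{i + 1}" for i in range(values.shape[1])]
            df = pd.DataFrame(values, columns=[str(n) for n in variable_names])
        validate_data(df)
        self.data = df
        self.nobs = df.shape[0]
        self.nvar = df.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ModuleStabilityModel":
        return cls(df)

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> "ModuleStabilityModel":
        return cls(read_data(path, delimiter=delimiter))

    def correlation(self) -> pd.DataFrame:
        """Pearson correlation matrix of the variables."""
        return pearson_correlation(self.data)

    def fit(
        self,
        thresholds=SIMULATION_GRID,
        B: int = 100,
        m: int = 50,
        seed=None,
    ) -> "ModuleStabilityResults":
        """Run the stability profile and select the optimal threshold.

        Parameters
        ----------
        thresholds : ascending grid of candidate correlation thresholds
        B : bootstrap replicates per threshold
        m : degree-preserving null graphs per threshold
        seed : master seed for all randomness
        """
        profile = stability_profile(
            self.data, thresholds=thresholds, B=B, m=m, seed=seed, keep_reports=True
        )
        return ModuleStabilityResults(self, profile)

    def stability(self, t: float, B: int = 100, seed=None) -> StabilityReport:
        """Conditional stability report at a single fixed threshold."""
        ensemble = bootstrap_modules(self.data, t, B=B, seed=np.random.default_rng(seed))
        return stability_report(ensemble)


class ModuleStabilityResults:
    """Results of a fitted module-stability profile.

    Attributes
    ----------
    profile : StabilityProfile
        Per-threshold S_obs, E[S_null], S_delta and diagnostics.
    t_opt : float
        Threshold maximizing S_delta (ties toward the smaller t).
    modules_ : ModuleSet
        Modules detected on the full data at ``t_opt``.
    report_ : StabilityReport
        Node/module/overall stability conditional on ``modules_``.
    """

    def __init__(self, model: ModuleStabilityModel, profile: StabilityProfile):
        self.model = model
        self.profile = profile
        self.t_opt = profile.t_opt
        idx = profile.opt_index
        self.modules_ = profile.reference_modules[idx]
        self.report_ = profile.reports[idx] if profile.reports else None

    def graph_at(self, t: float):
        """Thresholded correlation graph of the full data at ``t``."""
        return threshold_graph(self.model.correlation(), t)

    def modules_at(self, t: float) -> ModuleSet:
        return fast_greedy_modules(self.graph_at(t))

    def summary(self) -> str:
        """Plain-text summary table of the profile and the selected optimum."""
        prof = self.profile
        lines = [
            "Module stability profile",
            "=" * 64,
            f"observations: {self.model.nobs}    variables: {self.model.nvar}",
            f"bootstraps B: {prof.B}    null graphs m: {prof.m}",
            "-" * 64,
            f"{'t':>6} {'S_obs':>8} {'E[S_null]':>10} {'S_delta':>9} {'edges':>7} {'modules':>8}",
        ]
        for l, t in enumerate(prof.thresholds):
            mark = "  <- t_opt" if t == prof.t_opt else ""
            lines.append(
                f"{t:>6.2f} {prof.s_obs[l]:>8.4f} {prof.s_null[l]:>10.4f} "
                f"{prof.s_delta[l]:>9.4f} {prof.n_edges[l]:>7d} {prof.n_modules[l]:>8d}{mark}"
            )
        lines.append("-" * 64)
        lines.append(
            f"selected t_opt = {self.t_opt:.2f}: {self.modules_.n_modules} modules, "
            f"overall stability {self.report_.overall:.4f}"
            if self.report_ is not None
            else f"selected t_opt = {self.t_opt:.2f}: {self.modules_.n_modules} modules"
        )
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        return self.profile.plot(ax=ax)

    def save(self, outdir) -> dict:
        """Write profile, report, modules, edge list and metadata to ``outdir``.

        Returns the mapping of artifact names to paths.
        """
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "profile_csv": os.path.join(outdir, "profile.csv"),
            "profile_json": os.path.join(outdir, "profile.json"),
            "modules_tsv": os.path.join(outdir, "modules_topt.tsv"),
            "edges_tsv": os.path.join(outdir, "edges_topt.tsv"),
            "metadata_json": os.path.join(outdir, "run_metadata.json"),
        }
        self.profile.write_csv(paths["profile_csv"])
        self.profile.write_json(paths["profile_json"])
        self.modules_.write_tsv(paths["modules_tsv"])
        self.graph_at(self.t_opt).write_edgelist(paths["edges_tsv"])
        if self.report_ is not None:
            paths["report_json"] = os.path.join(outdir, "stability_topt.json")
            self.report_.write_json(paths["report_json"])
        for l, rep in enumerate(self.profile.reports):
            key = f"report_t{self.profile.thresholds[l]:.2f}"
            paths[key] = os.path.join(
                outdir, f"stability_t{self.profile.thresholds[l]:.2f}.json"
            )
            rep.write_json(paths[key])
        import netstab

        meta = {
            "netstab_version": netstab.__version__,
            "seed": self.profile.seed if isinstance(self.profile.seed, (int, type(None))) else str(self.profile.seed),
            "B": self.profile.B,
            "m": self.profile.m,
            "thresholds": self.profile.thresholds.tolist(),
            "t_opt": self.t_opt,
            "n_observations": self.model.nobs,
            "n_variables": self.model.nvar,
        }
        with open(paths["metadata_json"], "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        return paths
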