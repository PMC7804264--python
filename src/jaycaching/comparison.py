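"""Model-comparison front end: a fittable model object and a results object.

:class:`CachingModelComparison` bundles an observation table with a
candidate model enumeration; ``fit()`` computes every marginal likelihood
and returns :class:`ModelComparisonResults` holding the posterior table,
Monte-Carlo standard errors, and presentation helpers (``summary()``,
``to_frame()``, ``to_json()``, ASCII posterior bars).
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from . import data as _data
from .data import ObservationTable, exclude_bird
from .inference import DEFAULT_MC_SAMPLES, PosteriorTable, model_posterior
from .models import ModelSpec, enumerate_models

__all__ = ["CachingModelComparison", "ModelComparisonResults"]


class CachingModelComparison:
    """Bayesian comparison of caching-rate models for one experiment.

    Parameters
    ----------
    table
        Validated observation table (see :mod:`jaycaching.data`).
    models
        Candidate models; defaults to the full enumeration for the
        table's experiment (13 two-food / 9 food-absence models).

    Examples
    --------
    >>> comp = CachingModelComparison.from_fixture("table1")
    >>> res = comp.fit(n_samples=100_000, seed=7)
    >>> round(res.posterior("food+bird"), 3)
    0.997
    """

    def __init__(
        self, table: ObservationTable, models: Sequence[ModelSpec] | None = None
    ):
        self.table = table
        self.models = tuple(
            models if models is not None else enumerate_models(table.experiment)
        )

    @classmethod
    def from_csv(cls, path, experiment: str) -> "CachingModelComparison":
        return cls(_data.read_observations(path, experiment))

    @classmethod
    def from_fixture(cls, name: str) -> "CachingModelComparison":
        """Build from a packaged dataset (``"table1"`` or ``"table2"``)."""
        return cls(_data.load_fixture(name))

    def exclude(self, *bird_ids: str) -> "CachingModelComparison":
        """A new comparison without the given birds (original unchanged)."""
        table = self.table
        for bird in bird_ids:
            table = exclude_bird(table, bird)
        return CachingModelComparison(table, self.models)

    def fit(
        self,
        n_samples: int = DEFAULT_MC_SAMPLES,
        seed: int | None = None,
        include_coefficients: bool = True,
    ) -> "ModelComparisonResults":
        """Compute all marginal likelihoods and normalise.

        ``n_samples`` is the number of Dirichlet draws per constrained
        posterior-mass estimate; ``seed`` makes the fit reproducible.
        """
        post = model_posterior(
            self.table, self.models, n_samples, seed, include_coefficients
        )
        return ModelComparisonResults(self, post, n_samples=n_samples, seed=seed)


class ModelComparisonResults:
    """Fitted posterior model probabilities plus diagnostics."""

    def __init__(
        self,
        model: CachingModelComparison,
        posterior_table: PosteriorTable,
        n_samples: int,
        seed: int | None,
    ):
        self.model = model
        self.posterior_table = posterior_table
        self.n_samples = n_samples
        self.seed = seed

    # -- accessors -----------------------------------------------------
    def posterior(self, model_id: str) -> float:
        return self.posterior_table.posterior(model_id)

    @property
    def posteriors(self) -> dict[str, float]:
        return self.posterior_table.posteriors

    @property
    def log_ml(self) -> dict[str, float]:
        return self.posterior_table.log_ml

    def hypothesis_max(self, family: str) -> float:
        """Highest posterior among a hypothesis's variants (``FPH``, ``FPH1``,
        ``FPH2`` or ``CCH``)."""
        return self.posterior_table.hypothesis_max(family)

    @property
    def best_model(self) -> str:
        return self.posterior_table.sorted_entries()[0][0].model_id

    # -- presentation --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per model, sorted by posterior probability."""
        rows = []
        for m, r, p in self.posterior_table.sorted_entries():
            rows.append(
                {
                    "model": m.model_id,
                    "hypothesis": m.hypothesis or "",
                    "method": r.method,
                    "log_ml": r.log_ml,
                    "mc_se_log": r.mc_se_log,
                    "posterior": p,
                }
            )
        return pd.DataFrame(rows)

    def summary(self, precision: int = 4) -> str:
        """Human-readable posterior table."""
        frame = self.to_frame()
        frame["posterior"] = frame["posterior"].map(lambda p: f"{p:.{precision}g}")
        frame["log_ml"] = frame["log_ml"].map(lambda v: f"{v:.4f}")
        frame["mc_se_log"] = frame["mc_se_log"].map(
            lambda v: "" if pd.isna(v) else f"{v:.2g}"
        )
        header = (
            f"Bayesian model comparison — experiment: {self.posterior_table.experiment}\n"
            f"birds: {', '.join(self.model.table.bird_ids)}\n"
            f"MC samples per constrained mass: {self.n_samples}; seed: {self.seed}\n"
        )
        return header + frame.to_string(index=False)

    def bars(self, width: int = 40) -> str:
        """ASCII bar rendering of the posterior probabilities."""
        lines = []
        for m, _, p in self.posterior_table.sorted_entries():
            bar = "#" * max(1 if p > 0 else 0, round(p * width))
            lines.append(f"{m.model_id:>16s} {p:8.5f} {bar}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "experiment": self.posterior_table.experiment,
            "data_fingerprint": self.posterior_table.data_fingerprint,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "birds": list(self.model.table.bird_ids),
            "models": [
                {
                    "model_id": m.model_id,
                    "hypothesis": m.hypothesis,
                    "method": r.method,
                    "log_ml": r.log_ml,
                    "mc_se_log": r.mc_se_log,
                    "posterior": p,
                }
                for m, r, p in self.posterior_table.entries
            ],
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text
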