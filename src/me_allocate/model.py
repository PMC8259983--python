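"""Model/Results facade over the ME machinery.

:class:`MEModel` wraps a coupled :class:`~me_allocate.core.MEModelSpec`
together with a media condition, in the style of a statsmodels model object:
``MEModel(spec, media).fit()`` returns an :class:`MEResults` carrying the
optimal growth rate, the parsimonious flux vector, solver diagnostics and a
``summary()`` table, with biomass-composition and protein-allocation
accessors hanging off the results.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CoenzymeSpec, MEModelSpec
from .conditions import MediaCondition, apply_media
from .demand import (
    amino_acid_demand,
    coenzyme_demand,
    component_classes,
    normalize_composition,
    prosthetic_demand,
)
from .limitation import protein_allocation
from . import solver as _solver

__all__ = ["MEModel", "MEResults"]


class MEModel:
    """A growth-maximisation problem: coupled ME network plus media.

    Parameters
    ----------
    spec : MEModelSpec
        A model with coupling constraints applied (e.g. from
        :func:`me_allocate.synthetic.generate_toy_me_model` or
        :meth:`from_json`).
    media : MediaCondition, optional
        Exchange bounds to impose; when omitted the spec's stored bounds
        are used as-is.
    coenzymes : sequence of CoenzymeSpec, optional
        Defaults to the coenzymes stored on the spec.
    """

    def __init__(self, spec: MEModelSpec, media: Optional[MediaCondition] = None,
                 coenzymes: Optional[Sequence[CoenzymeSpec]] = None):
        self.spec = spec
        self.media = media
        self.coenzymes = list(coenzymes if coenzymes is not None
                              else spec.coenzymes)

    @classmethod
    def from_json(cls, path: str, media: Optional[MediaCondition] = None
                  ) -> "MEModel":
        return cls(MEModelSpec.from_json(path), media=media)

    def fit(self, mu_hi: float = _solver.DEFAULT_MU_HI,
            tol: float = _solver.DEFAULT_TOL) -> "MEResults":
        """Maximise growth by bisection; returns the results object."""
        work = self.spec.copy()
        if self.media is not None:
            apply_media(work, self.media)
        solution = _solver.maximize_growth(work, mu_hi=mu_hi, tol=tol)
        return MEResults(self, work, solution, tol=tol)


class MEResults:
    """Optimal growth state of an :class:`MEModel`.

    Attributes
    ----------
    growth_rate : float
        The maximal feasible growth rate mu* (h^-1).
    fluxes : pandas.Series
        Parsimonious flux vector at mu* (mmol/gDW/h; protein-biomass flux
        in g/gDW/h).
    """

    def __init__(self, model: MEModel, fitted_spec: MEModelSpec,
                 solution: _solver.MESolution, tol: float):
        self.model = model
        self.spec = fitted_spec
        self.solution = solution
        self.tol = tol

    # -- estimates ---------------------------------------------------------
    @property
    def growth_rate(self) -> float:
        return self.solution.mu_opt

    @property
    def fluxes(self) -> pd.Series:
        return self.solution.fluxes

    @property
    def status(self) -> str:
        return self.solution.status

    # -- diagnostics -------------------------------------------------------
    def coupling_residuals(self) -> pd.Series:
        """Relative residual of every species-balance row at the optimum."""
        return _solver.coupling_residuals(self.spec, self.solution)

    def max_residual(self) -> float:
        res = self.coupling_residuals()
        return float(res.max()) if len(res) else 0.0

    # -- derived quantities ------------------------------------------------
    def biomass_composition(self, normalization: str = "per_protein_biomass"):
        """Normalized synthesis demands of amino acids, prosthetic groups
        and coenzymes at the optimum."""
        raw: dict[str, float] = {}
        raw.update(amino_acid_demand(self.solution, self.spec))
        raw.update(prosthetic_demand(self.solution, self.spec))
        raw.update(coenzyme_demand(self.solution, self.model.coenzymes))
        media = self.model.media
        return normalize_composition(
            raw, self.solution, self.spec, mode=normalization,
            condition_id=media.condition_id if media else "stored_bounds",
            aerobic=media.aerobic if media else True,
            element_class=media.element_class if media else "C")

    def protein_allocation(self) -> dict[str, float]:
        """Protein mass fraction per metabolic subsystem."""
        return protein_allocation(self.solution, self.spec)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        sol = self.solution
        lines = [
            "ME growth maximisation",
            "=" * 46,
            f"{'status':<28}{sol.status}",
            f"{'growth rate mu* (1/h)':<28}{sol.mu_opt:.6f}",
            f"{'bisection iterations':<28}{sol.iterations}",
            f"{'bracket (feasible, infeas.)':<28}"
            f"({sol.bracket[0]:.6g}, {sol.bracket[1]:.6g})",
            f"{'tolerance (1/h)':<28}{self.tol:g}",
            f"{'max balance residual':<28}{self.max_residual():.3e}",
            "-" * 46,
        ]
        comp = None
        if sol.status == "optimal" and sol.mu_opt > 0:
            try:
                comp = self.biomass_composition()
            except Exception:  # pragma: no cover - degenerate toy inputs
                comp = None
        if comp is not None:
            classes = component_classes(self.spec, self.model.coenzymes)
            lines.append("normalized synthesis demand (per g protein):")
            for cid, value in sorted(comp.demands.items()):
                if classes.get(cid) in ("coenzyme", "prosthetic"):
                    lines.append(f"  {cid:<20}{value:12.4e}  "
                                 f"{classes.get(cid, '')}")
        return "\n".join(lines)

    def plot_composition(self, ax=None, normalization: str =
                         "per_protein_biomass"):
        """Bar plot of the normalized biomass composition."""
        import matplotlib.pyplot as plt

        comp = self.biomass_composition(normalization=normalization)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        items = sorted(comp.demands.items())
        names = [k for k, _ in items]
        vals = np.array([max(v, 0.0) for _, v in items])
        ax.bar(range(len(names)), vals)
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=90, fontsize=7)
        ax.set_yscale("log")
        ax.set_ylabel(f"demand ({comp.normalization})")
        return ax
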