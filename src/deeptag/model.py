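"""Model/Results interface for the factorial NB analysis.

:class:`TagCountModel` is built from a gene x sample count matrix with the
2x2 genotype x treatment sample layout; :meth:`TagCountModel.fit` runs TMM
normalization, Cox-Reid dispersion estimation with shrinkage, and the
likelihood-ratio tests of the genotype, treatment and interaction effects,
returning a :class:`TagCountResults` that carries the per-gene tables,
normalization factors, dispersion model, assembled effect lists, a
``summary()`` and the interaction-pattern clustering entry point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from deeptag import clustering, deglm
from deeptag.containers import CountMatrix

logger = logging.getLogger(__name__)


class TagCountModel:
    """NB factorial model (log link) for a 2x2 tag-count experiment.

    Model A (additive: intercept + genotype + treatment) tests each main
    effect by dropping its column; model B (full factorial with intercept)
    tests the interaction by dropping the product column.  Dispersions are
    estimated once, on the full factorial design, and reused for both
    models.  Genes with all-zero counts are excluded from fitting and
    reported separately on the results object.
    """

    def __init__(self, data: CountMatrix):
        if not data.has_complete_design():
            raise ValueError("all four genotype x treatment groups are required")
        self.data, self.zero_genes = data.drop_all_zero_genes()
        self.design_additive = deglm.build_design(self.data.samples, "additive")
        self.design_interaction = deglm.build_design(self.data.samples, "interaction")

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        chromosomes: pd.Series | None = None,
    ) -> "TagCountModel":
        return cls(CountMatrix(counts, samples, chromosomes))

    def fit(
        self,
        alpha: float = 0.005,
        prior_n: float = 10.0,
        exclude_chromosomes: tuple[str, ...] = ("8",),
        interaction_exclusion: bool = True,
        dispersion: str = "tagwise",
    ) -> "TagCountResults":
        """Run normalization, dispersion estimation and the three LRTs."""
        counts = self.data
        factors = deglm.tmm_factors(counts)
        offset = np.log(counts.library_sizes.to_numpy(dtype=float) * factors.to_numpy())
        disp_model = deglm.estimate_dispersions(
            counts, self.design_interaction, offset=offset, prior_n=prior_n
        )
        phi = {
            "tagwise": disp_model.tagwise,
            "trended": disp_model.trended,
            "common": disp_model.common,
        }[dispersion]
        add = self.design_additive
        tests = {
            "genotype": deglm.lrt_test(
                counts, add, add.drop(columns="genotype"), phi, offset, coef="genotype"
            ),
            "csd": deglm.lrt_test(
                counts, add, add.drop(columns="treatment"), phi, offset, coef="treatment"
            ),
            "interaction": deglm.lrt_test(
                counts,
                self.design_interaction,
                self.design_interaction.drop(columns="genotype:treatment"),
                phi,
                offset,
                coef="genotype:treatment",
            ),
        }
        lists = None
        if counts.chromosomes is not None:
            lists = deglm.assemble_effect_lists(
                tests["genotype"],
                tests["csd"],
                tests["interaction"],
                counts.chromosomes,
                alpha=alpha,
                exclude_chromosomes=exclude_chromosomes,
                interaction_exclusion=interaction_exclusion,
            )
        return TagCountResults(
            model=self,
            norm_factors=factors,
            dispersions=disp_model,
            tests=tests,
            effect_lists=lists,
            alpha=alpha,
        )


@dataclass
class TagCountResults:
    """Fitted factorial analysis: tables, factors, dispersions, lists."""

    model: TagCountModel
    norm_factors: pd.Series
    dispersions: deglm.DispersionModel
    tests: dict[str, pd.DataFrame]
    effect_lists: deglm.EffectLists | None
    alpha: float
    _patterns: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def data(self) -> CountMatrix:
        return self.model.data

    def log_cpm(self, prior_count: float = 0.5) -> pd.DataFrame:
        """log2 counts per million on TMM-scaled library sizes."""
        counts = self.data.counts
        eff = self.data.library_sizes * self.norm_factors
        return np.log2((counts + prior_count).div(eff + 1.0, axis=1) * 1e6)

    def de_table(self, effect: str) -> pd.DataFrame:
        return self.tests[effect]

    def interaction_patterns(self) -> pd.DataFrame:
        """Standardized 4-group mean profiles of the interaction-list genes."""
        if self.effect_lists is None:
            raise ValueError("effect lists unavailable (no chromosome annotation)")
        genes = sorted(self.effect_lists.interaction)
        return clustering.standardize_patterns(self.log_cpm(), self.data.samples, genes)

    def cluster_interaction_patterns(
        self, k: int = 4, restarts: int = 50, seed: int | None = 0
    ) -> tuple[pd.DataFrame, clustering.ClusterAssignment]:
        """Correlation-distance k-means over the interaction-gene patterns."""
        patterns = self.interaction_patterns()
        return patterns, clustering.kmeans_patterns(patterns, k=k, restarts=restarts, seed=seed)

    def summary(self) -> str:
        lines = [
            "Factorial NB tag-count analysis",
            "=" * 47,
            f"genes fitted:          {len(self.data.genes)}",
            f"all-zero genes:        {len(self.model.zero_genes)}",
            f"samples:               {len(self.data.sample_ids)}",
            f"common dispersion:     {self.dispersions.common:.4g}",
            f"tagwise dispersion:    median {self.dispersions.tagwise.median():.4g} "
            f"(prior n = {self.dispersions.prior_n:g})",
            f"significance level:    p <= {self.alpha:g} (nominal)",
        ]
        for effect, table in self.tests.items():
            n_sig = int((table["p_value"] <= self.alpha).sum())
            lines.append(f"{effect + ' effect:':<23}{n_sig} genes at p <= {self.alpha:g}")
        if self.effect_lists is not None:
            el = self.effect_lists
            lines += [
                "after list assembly (chromosome "
                + ",".join(el.excluded_chromosomes)
                + " and interaction-overlap removal):",
                f"  genotype list:       {len(el.genotype)}",
                f"  csd list:            {len(el.csd)}",
                f"  interaction list:    {len(el.interaction)}",
            ]
        return "\n".join(lines)
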