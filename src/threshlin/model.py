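"""Estimator-style front end for the threshold-linear animal model.

`ThresholdLinearModel` follows scikit-learn's estimator conventions
(constructor stores hyperparameters, ``fit`` learns, fitted attributes carry
a trailing underscore, ``get_params``/``set_params`` work), so model settings
can be cloned and varied programmatically.  Input is pedigree-structured
(records + pedigree) rather than a feature matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import posterior
from .gibbs import ChainConfig, PriorConfig, _run
from .pedigree import Pedigree
from .records import KitRecord, ModelSpec, build_design


class ThresholdLinearModel(BaseEstimator):
    """Bayesian three-trait threshold-linear animal model.

    Fits survival at birth and at weaning (threshold traits on the liability
    scale) jointly with birth weight (Gaussian) by Gibbs sampling, with
    direct genetic, maternal permanent environmental and common litter
    random effects.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        Chain length, discarded prefix and saving interval.  The defaults
        are the full-analysis settings (1,000,000 / 500,000 / 100); reduced
        chains (e.g. 20,000 / 5,000 / 10) are adequate for synthetic checks.
    seed : int
        Seed for every source of randomness in the chain.
    adjust_for_litter_size : bool
        Add total number born as a centered covariate to all traits.
    flat_priors : bool
        Use improper reference priors for the covariance matrices instead of
        the default weakly-informative inverse Wisharts.
    prior_df : float
        Degrees of freedom of the proper inverse Wishart priors.
    block_a_every : int
        Interval (iterations) of the joint additive-genetic block redraw;
        0 disables it (single-site updates only).

    Attributes
    ----------
    samples_ : PosteriorSamples
        Thinned post-burn-in draws of covariance entries and derived
        parameters.
    summary_ : pandas.DataFrame
        Posterior means, 95% HPD bounds, sign probabilities, Geweke Z, MCSE.
    breeding_values_ : pandas.DataFrame
        Posterior-mean additive genetic values, one row per pedigree animal.
    design_ : DesignMatrices
    """

    def __init__(self, n_iter: int = 1_000_000, burn_in: int = 500_000,
                 thin: int = 100, seed: int = 0,
                 adjust_for_litter_size: bool = False,
                 flat_priors: bool = False, prior_df: float = 5.0,
                 block_a_every: int = 5):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.adjust_for_litter_size = adjust_for_litter_size
        self.flat_priors = flat_priors
        self.prior_df = prior_df
        self.block_a_every = block_a_every

    def fit(self, records: list[KitRecord], pedigree: Pedigree,
            y=None) -> "ThresholdLinearModel":
        """Run the Gibbs sampler on kit records linked to a pedigree."""
        spec = ModelSpec(adjust_for_litter_size=self.adjust_for_litter_size)
        design = build_design(records, pedigree, spec)
        cfg = ChainConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            seed=self.seed, block_a_every=self.block_a_every,
            priors=PriorConfig(df=self.prior_df, flat=self.flat_priors))
        samples, ebv, _ = _run(design, pedigree, cfg)
        self.design_ = design
        self.samples_ = samples
        self.summary_ = posterior.summarize(samples) if len(samples) >= 100 else None
        self.breeding_values_ = pd.DataFrame(
            ebv, index=pd.Index(pedigree.ids, name="animal"),
            columns=list(design.trait_names))
        return self

    def posterior_mean(self, parameter: str) -> float:
        """Posterior mean of one stored or derived parameter."""
        if not hasattr(self, "samples_"):
            raise AttributeError("model is not fitted")
        return float(np.nanmean(self.samples_.draws[parameter].to_numpy()))

    def report(self) -> str:
        """Triangular tables of fractions and correlations."""
        if self.summary_ is None:
            raise AttributeError("not enough saved draws for a summary")
        return posterior.render_tables(self.summary_,
                                       tuple(self.design_.trait_names))
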