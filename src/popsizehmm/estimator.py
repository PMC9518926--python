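"""Scikit-learn style estimator facade over the EM engine."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .demography import DemographicModel, log_spaced_change_points
from .em_engine import (EMConfig, SubsetScheme, build_matrices, build_subsets,
                        initial_model_from_data, run_em)
from .hmm_core import forward_backward_skipping
from .simdata import SiteData


class PopulationSizeHMM(BaseEstimator):
    """Coalescent-HMM estimator of piecewise-constant size history.

    The hidden state at each base is the discretized height (``tmrca``) or
    total branch length (``length``) of the local genealogy; emissions are
    derived-allele counts.  Fitting runs an EM algorithm whose M-step
    maximizes the expected complete-data log-likelihood over log
    coalescent rates by Nelder-Mead search, with the likelihood composited
    over haplotype subsets of the configured sizes.

    Parameters
    ----------
    mu, r : float
        Per-generation per-site mutation and recombination probabilities.
    hidden_state : {"tmrca", "length"}
    subset_sizes : tuple of int
        Non-overlapping random subsets of each size enter the composite
        likelihood; ignored when ``subsets`` is given explicitly.
    change_points_gen : array-like, optional
        Epoch start times in generations; alternatively give ``n_epochs``
        with ``epoch_min_gen``/``epoch_max_gen`` for log-spaced points.
    pseudo_haploid : bool
        Interpret the input haplotypes as pseudo-haploid calls and use the
        two-layer hypergeometric emission model (tree height of the
        underlying 2n haplotypes as hidden state).

    Attributes
    ----------
    model_ : DemographicModel
        Fitted demographic model (rates inverted and scaled to sizes via
        ``model_.size_history_table()``).
    history_ : list of dict
        Per-iteration composite log-likelihood and parameters.
    size_history_ : pandas.DataFrame
        Columns (generation_start, generation_end, N_diploid).
    """

    def __init__(self, mu=1.25e-8, r=1.25e-8, hidden_state="tmrca",
                 subset_sizes=(2, 10), subsets=None, change_points_gen=None,
                 n_epochs=None, epoch_min_gen=None, epoch_max_gen=None,
                 discretization_size=16, max_iters=None,
                 regularization_c12=0.0, pseudo_haploid=False,
                 initial_model=None, seed=0, convergence_tol=1e-6,
                 verbose=False):
        self.mu = mu
        self.r = r
        self.hidden_state = hidden_state
        self.subset_sizes = subset_sizes
        self.subsets = subsets
        self.change_points_gen = change_points_gen
        self.n_epochs = n_epochs
        self.epoch_min_gen = epoch_min_gen
        self.epoch_max_gen = epoch_max_gen
        self.discretization_size = discretization_size
        self.max_iters = max_iters
        self.regularization_c12 = regularization_c12
        self.pseudo_haploid = pseudo_haploid
        self.initial_model = initial_model
        self.seed = seed
        self.convergence_tol = convergence_tol
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _as_data(self, X):
        data = [X] if isinstance(X, SiteData) else list(X)
        if not data:
            raise ValueError("no input chromosomes")
        n = data[0].n_haplotypes
        if any(d.n_haplotypes != n for d in data):
            raise ValueError("all chromosomes must share the haplotype panel")
        return data, n

    def _config(self) -> EMConfig:
        return EMConfig(max_iters=self.max_iters,
                        regularization_c12=self.regularization_c12,
                        convergence_tol=self.convergence_tol,
                        seed=self.seed,
                        discretization_size=self.discretization_size)

    def _initial_model(self, data, n) -> DemographicModel:
        if self.initial_model is not None:
            return self.initial_model
        if self.change_points_gen is not None:
            cps_gen = np.asarray(self.change_points_gen, dtype=float)
        elif self.n_epochs and self.n_epochs > 1:
            if not (self.epoch_min_gen and self.epoch_max_gen):
                raise ValueError("n_epochs needs epoch_min_gen and "
                                 "epoch_max_gen")
            cps_gen = None
        else:
            cps_gen = np.array([])
        base = initial_model_from_data(data, n, self.mu, self.r)
        if cps_gen is None:
            cps = log_spaced_change_points(self.epoch_min_gen,
                                           self.epoch_max_gen,
                                           self.n_epochs - 1, base.N0)
        else:
            cps = cps_gen / (2.0 * base.N0)
        return DemographicModel(cps, np.zeros(len(cps) + 1), base.N0,
                                self.mu, self.r)

    def _scheme(self, n) -> SubsetScheme:
        if self.subsets is not None:
            return build_subsets(n, subsets=self.subsets)
        return build_subsets(n, sizes=list(self.subset_sizes),
                             seed=self.seed)

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the size history to one or more chromosomes of SiteData."""
        data, n = self._as_data(X)
        model0 = self._initial_model(data, n)
        scheme = self._scheme(n)
        model, history = run_em(data, scheme, model0,
                                hidden_state=self.hidden_state,
                                config=self._config(),
                                pseudo_haploid=self.pseudo_haploid,
                                verbose=self.verbose)
        self.model_ = model
        self.history_ = history
        self.n_iter_ = len(history)
        self.log_likelihood_ = history[-1]["composite_log_likelihood"]
        self.size_history_ = model.size_history_table()
        self.scheme_ = scheme
        return self

    def score(self, X, y=None) -> float:
        """Composite log-likelihood of data under the fitted model."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        data, n = self._as_data(X)
        scheme = self._scheme(n)
        total = 0.0
        from .demography import length_discretization, tmrca_discretization
        disc_fn = (tmrca_discretization if self.hidden_state == "tmrca"
                   else length_discretization)
        for n_s in scheme.distinct_sizes:
            n_build = 2 * n_s if self.pseudo_haploid else n_s
            disc = disc_fn(self.discretization_size, n_build, self.model_)
            A, B, Pi = build_matrices(self.model_, n_s, disc,
                                      self.hidden_state, self.pseudo_haploid,
                                      config=self._config())
            for subset in scheme.of_size(n_s):
                for chrom in data:
                    total += forward_backward_skipping(
                        chrom.observations(subset), A, B, Pi).log_likelihood
        return total

    def predict_history(self, k_generations):
        """Diploid size N(k) of the fitted model at the given generations."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return self.model_.size_at(np.asarray(k_generations, dtype=float))

    def decode(self, X, subset=None):
        """Posterior hidden-state marginals per run for each chromosome.

        Returns a list of (ObservationSequence, posterior array) pairs;
        the posterior row for a run is the state distribution at its
        first locus.
        """
        from sklearn.utils.validation import check_is_fitted
        from .demography import length_discretization, tmrca_discretization

        check_is_fitted(self, "model_")
        data, n = self._as_data(X)
        subset = tuple(subset) if subset is not None else tuple(range(n))
        n_s = len(subset)
        disc_fn = (tmrca_discretization if self.hidden_state == "tmrca"
                   else length_discretization)
        n_build = 2 * n_s if self.pseudo_haploid else n_s
        disc = disc_fn(self.discretization_size, n_build, self.model_)
        A, B, Pi = build_matrices(self.model_, n_s, disc, self.hidden_state,
                                  self.pseudo_haploid,
                                  config=self._config())
        out = []
        for chrom in data:
            obs = chrom.observations(subset)
            _, post = forward_backward_skipping(obs, A, B, Pi,
                                                return_posterior=True)
            out.append((obs, post))
        return out
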