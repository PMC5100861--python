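"""Small phylogenetic post-processing utilities.

* Harmonic-mean Bayes-factor comparison of two MCMC runs (e.g. relaxed vs
  strict molecular clock): each chain's marginal log-likelihood is
  estimated by the harmonic mean of its post-burn-in likelihood samples,
  computed in log space, and the comparison is reported on the
  2*ln(BF) scale (Kass-Raftery convention); the raw BF is exp of half that.

* Rescaling of posterior chronograms to a calibrated root age: when a
  dating run is unconstrained, each posterior tree is made absolute by
  drawing a root age from a normal prior (default mean 65 MY, SD 4.62 MY,
  truncated at zero) and scaling every node age proportionally, so relative
  node depths are preserved exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
from scipy.special import logsumexp

from .errors import ChronogramError, TraceError


@dataclass
class LikelihoodTrace:
    """Ordered post-burn-in log-likelihood samples from one chain."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise TraceError("empty likelihood trace")
        if not np.all(np.isfinite(self.values)):
            raise TraceError("likelihood trace contains non-finite values")


def read_loglik_trace(path: str) -> LikelihoodTrace:
    """One float per line (post burn-in by contract)."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                values.append(float(line))
    return LikelihoodTrace(np.asarray(values))


def log_harmonic_mean(trace: LikelihoodTrace) -> float:
    """log of the harmonic mean of likelihoods, from log-likelihood samples.

    HM = n / sum(1/L_i), so log HM = log n - logsumexp(-loglik); the
    subtraction stays in log space for numerical stability.
    """
    ll = trace.values
    return float(math.log(ll.size) - logsumexp(-ll))


def harmonic_mean_bf(trace_a: LikelihoodTrace, trace_b: LikelihoodTrace) -> float:
    """2*ln Bayes factor of model a over model b; positive favors a."""
    return 2.0 * (log_harmonic_mean(trace_a) - log_harmonic_mean(trace_b))


# ---------------------------------------------------------------------------
# Chronogram rescaling
# ---------------------------------------------------------------------------

ULTRAMETRIC_RTOL = 1e-9


def root_age(tree: dendropy.Tree) -> float:
    """Root-to-tip depth of an ultrametric tree, validated within tolerance."""
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    if not depths:
        raise ChronogramError("tree has no leaves")
    age = max(depths)
    if age <= 0:
        raise ChronogramError("tree has zero root-to-tip depth")
    if (age - min(depths)) > ULTRAMETRIC_RTOL * age + 1e-12:
        raise ChronogramError(
            f"tree is not ultrametric (tip depths span "
            f"[{min(depths):g}, {max(depths):g}])"
        )
    return age


def rescale_chronogram(tree: dendropy.Tree, root_age_mean: float = 65.0,
                       root_age_sd: float = 4.62,
                       seed: Optional[int] = None,
                       drawn_age: Optional[float] = None) -> dendropy.Tree:
    """Scale all node ages so the root sits at a drawn (or given) age.

    The age is drawn from Normal(root_age_mean, root_age_sd) truncated at
    zero by rejection (negligible mass at the defaults).  Every branch
    length is multiplied by drawn_age / current_root_age, preserving
    topology and relative node depths exactly.
    """
    current = root_age(tree)
    if drawn_age is None:
        rng = np.random.default_rng(seed)
        while True:
            drawn_age = float(rng.normal(root_age_mean, root_age_sd))
            if drawn_age > 0:
                break
    factor = drawn_age / current
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return scaled
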