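"""Genome length, coverage and map-saturation estimators.

A genetic map only samples the recombinogenic genome.  Three standard
summary statistics quantify how completely it does so:

- *expected genome length* per linkage group, inflating the observed length
  ``L_obs`` of a group carrying ``m`` loci by ``(m + 1)/(m - 1)`` under the
  assumption that loci are randomly distributed along the chromosome
  (the "Method 4" estimator of the map-length literature);
- *genome coverage*, the ratio of summed observed to summed expected length;
- *map saturation*, the expected proportion of the genome lying within
  ``d`` cM of at least one of ``n`` randomly placed loci on a genome of
  total length ``G``: ``c = 1 - exp(-2 d n / G)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["method4_expected", "coverage", "saturation"]


def method4_expected(l_obs: float, m: int) -> float:
    """Expected linkage-group length from observed length and locus count.

    Parameters
    ----------
    l_obs : float
        Observed map length of the group in cM (Kosambi or otherwise).
    m : int
        Number of mapped loci on the group; must be at least 2.

    Returns
    -------
    float
        ``l_obs * (m + 1) / (m - 1)``, in cM.
    """
    if m < 2:
        raise ValueError(f"need at least 2 loci to estimate expected length, got m={m}")
    if l_obs < 0:
        raise ValueError("observed length must be non-negative")
    return l_obs * (m + 1) / (m - 1)


def coverage(g_obs: float, g_est: float) -> float:
    """Genome coverage: observed over expected total map length."""
    if g_est <= 0:
        raise ValueError("expected genome length must be positive")
    return g_obs / g_est


def saturation(n: int, g: float, d: float) -> float:
    """Proportion of a genome of length ``g`` cM within ``d`` cM of a locus.

    Assumes ``n`` loci dropped uniformly at random on the genome, so the
    uncovered fraction decays exponentially: ``1 - exp(-2 d n / g)``.
    """
    if n < 1:
        raise ValueError("need at least one locus")
    if g <= 0:
        raise ValueError("genome length must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return float(1.0 - np.exp(-2.0 * d * n / g))
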