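"""Bundled worked-example data.

The activity-tracker contingency tables cross-tabulate the three true
activities (sitting, cross-trainer, cycling; 150 observations each,
450 total) against the partitions found by three clustering methods on
15×50 accelerometer matrices: modal (mean-shift) clustering, K-means,
and a mixture of matrix-variate Gaussians.  They are transcribed
verbatim from the published comparison table and serve as small exact
fixtures for the pair-counting indices.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ..metrics import ContingencyTable

__all__ = ["activity_contingency", "ACTIVITY_METHODS"]

ACTIVITY_METHODS = ("modal", "kmeans", "gmm")


def activity_contingency(method: str) -> ContingencyTable:
    """Load the activity-tracker table for 'modal', 'kmeans' or 'gmm'."""
    if method not in ACTIVITY_METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {ACTIVITY_METHODS}")
    with resources.files(__package__).joinpath(f"activity_{method}.csv").open() as fh:
        counts = np.loadtxt(fh, delimiter=",", dtype=int, ndmin=2)
    return ContingencyTable(counts)
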