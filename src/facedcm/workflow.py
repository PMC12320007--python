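"""Glue for running the whole pipeline on a cohort.

Fits every model of the space to every subject, collects the free-energy
evidence table, and hands it to group-level selection/averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inversion import Posterior, default_priors, invert
from .network_model import ModelSpec, build_model_space
from .synthetic_data import SubjectDataset

__all__ = ["fit_cohort"]


def fit_cohort(
    datasets: list[SubjectDataset],
    models: list[ModelSpec] | None = None,
    max_iter: int = 32,
    tol: float = 1e-2,
    verbose: bool = False,
) -> tuple[pd.DataFrame, list[list[Posterior]]]:
    """Invert each model for each subject.

    Returns the (subjects x models) free-energy table and the aligned
    grid of posteriors.
    """
    models = models or build_model_space()
    priors = {m.id: default_priors(m) for m in models}
    rows = []
    grid: list[list[Posterior]] = []
    for d in datasets:
        row = []
        posts = []
        for m in models:
            post = invert(
                m, priors[m.id], d.bold.bold, d.regressors,
                max_iter=max_iter, tol=tol,
            )
            row.append(post.free_energy)
            posts.append(post)
            if verbose:
                print(
                    f"{d.subject_id} {m.id}: F = {post.free_energy:.1f}, "
                    f"EV = {post.explained_var:.1f}%, iters = {post.n_iter}"
                )
        rows.append(row)
        grid.append(posts)
    evidence = pd.DataFrame(
        rows,
        index=[d.subject_id for d in datasets],
        columns=[m.id for m in models],
    )
    return evidence, grid
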