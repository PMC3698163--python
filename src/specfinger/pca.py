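"""Intra- and inter-class principal-component diagnostics.

Chemometric practice inspects class structure by projecting spectra on
leading eigenvectors.  Two variants are provided:

* intra-class: eigenvectors computed from each class separately (per
  spectral region), with *all* samples projected onto every class
  basis — with 2 regions, 2 classes and 4 components this yields the
  classic 2x8 = 16 coordinate columns;
* inter-class: one pooled eigenbasis per region.

Eigenvectors are sign-fixed (largest-magnitude loading positive) so
projections are reproducible across runs and BLAS builds.  A small
Gaussian-mixture BIC helper quantifies the "multiple clusters with an
overlapping mode" impression from 1-D projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .exceptions import CohortError


@dataclass
class PCAProjection:
    """Coordinates plus per-block eigensystem.

    ``block_map`` names every coordinate column as a tuple
    ``(kind, region_key, class_or_None, pc_index)``; blocks are stored
    under the same keys in ``eigenvectors`` / ``explained_variance``.
    """

    coordinates: np.ndarray
    eigenvectors: dict
    explained_variance: dict
    block_map: list[tuple]
    sample_ids: list[str]
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{kind}|{region}|{cls or 'common'}|PC{pc + 1}"
            for kind, region, cls, pc in self.block_map
        ]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "label", self.labels)
        return df


def _fix_signs(components: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1
            coords[:, k] *= -1
    return components, coords


def _fit_block(fit_X: np.ndarray, all_X: np.ndarray, n_components: int):
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(fit_X)
    coords = (all_X - pca.mean_) @ pca.components_.T
    comps, coords = _fix_signs(pca.components_.copy(), coords)
    return comps, pca.explained_variance_.copy(), coords


def intra_class_projection(
    features_by_region: dict,
    labels,
    n_components: int = 4,
    sample_ids=None,
) -> PCAProjection:
    """Per-class, per-region eigenbases; all samples projected on each.

    Eigenvectors come from the mean-centred data of one class restricted
    to one region; every sample (both classes) is projected onto every
    block.  Total coordinate dimension = n_regions x n_classes x
    n_components.
    """
    lab = np.asarray(labels, dtype=object)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(lab.size)]
    blocks, evs, exps, names = [], {}, {}, []
    for region, X in features_by_region.items():
        X = np.asarray(X, dtype=float)
        for cls in ("negative", "positive"):
            rows = np.where(lab == cls)[0]
            if rows.size < n_components + 1:
                raise CohortError(
                    f"class {cls!r} has {rows.size} samples; need "
                    f">= {n_components + 1} for {n_components} components"
                )
            comps, var, coords = _fit_block(X[rows], X, n_components)
            key = (str(region), cls)
            evs[key] = comps
            exps[key] = var
            blocks.append(coords)
            names += [("intra", str(region), cls, k) for k in range(n_components)]
    return PCAProjection(np.hstack(blocks), evs, exps, names, ids, list(lab))


def inter_class_projection(
    features_by_region: dict,
    labels,
    n_components: int = 4,
    sample_ids=None,
) -> PCAProjection:
    """Common (pooled-cohort) eigenbasis per region."""
    lab = np.asarray(labels, dtype=object)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(lab.size)]
    blocks, evs, exps, names = [], {}, {}, []
    for region, X in features_by_region.items():
        X = np.asarray(X, dtype=float)
        if X.shape[0] < n_components + 1:
            raise CohortError(
                f"cohort of {X.shape[0]} samples too small for "
                f"{n_components} components"
            )
        comps, var, coords = _fit_block(X, X, n_components)
        key = (str(region), "common")
        evs[key] = comps
        exps[key] = var
        blocks.append(coords)
        names += [("inter", str(region), None, k) for k in range(n_components)]
    return PCAProjection(np.hstack(blocks), evs, exps, names, ids, list(lab))


def bimodality_bic(x: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """BIC of 1- vs 2-component Gaussian mixtures on a 1-D projection.

    Returns ``(bic_1, bic_2)``; ``bic_2 < bic_1`` indicates that two
    modes describe the coordinate better than one.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed)
        gm.fit(x)
        bics.append(float(gm.bic(x)))
    return bics[0], bics[1]
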