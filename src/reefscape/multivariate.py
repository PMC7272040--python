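"""Zero-adjusted Bray-Curtis dissimilarities and distance-based linear models.

The fish assemblage (unit x species abundance or biomass matrix) is turned
into a Bray-Curtis dissimilarity matrix after appending a constant "dummy
species", which bounds dissimilarities between depauperate samples and makes
the distance between two all-zero samples zero. Marginal distance-based
linear model (DistLM) tests then relate the multivariate data cloud to one
covariate at a time via the pseudo-F statistic

    F = [tr(H G H) / q] / [tr((I - H) G (I - H)) / (n - q - 1)],

where G is the Gower-centred inner-product matrix of the dissimilarities and
H the hat matrix of the covariate (q = 1). Inference uses unrestricted
permutation of observation labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class MarginalTestResult:
    covariate: str
    pseudo_F: float
    prop_explained: float
    p_perm: float
    n_perm: int
    seed: int
    response: str = ""


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be exactly zero")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be non-negative")
    return D


def zero_adjusted_bray_curtis(abundance, dummy_value: float = 1.0) -> np.ndarray:
    """Bray-Curtis dissimilarities with a constant dummy species appended.

    ``BC(j, k) = sum|x_j - x_k| / sum(x_j + x_k)`` over all columns including
    the dummy. The dummy (default 1, the smallest possible abundance) keeps
    the denominator positive, so two all-zero samples have dissimilarity 0.
    """
    X = np.asarray(abundance, dtype=float)
    if isinstance(abundance, pd.DataFrame):
        X = abundance.to_numpy(dtype=float)
    if X.ndim != 2:
        raise ValueError("abundance must be a 2-D unit x species matrix")
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    if dummy_value <= 0:
        raise ValueError("dummy_value must be positive")
    Xa = np.column_stack([X, np.full(X.shape[0], float(dummy_value))])
    D = squareform(pdist(Xa, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    return D


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centred matrix G = -1/2 J (D o D) J with J = I - 11'/n.

    For Euclidean distances of centred points, G recovers their inner-product
    (Gram) matrix — the classical multidimensional-scaling identity.
    """
    D = _check_distance_matrix(D)
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def distlm_marginal(
    D: np.ndarray,
    covariate,
    n_perm: int = 9999,
    seed: int = 0,
    name: str = "covariate",
) -> MarginalTestResult:
    """Marginal DistLM test of one covariate against a dissimilarity matrix.

    The permutation p-value counts permuted pseudo-F values >= the observed
    one, with the observed statistic included: ``p = (count + 1) / (n_perm + 1)``.
    """
    D = _check_distance_matrix(D)
    x = np.asarray(covariate, dtype=float)
    n = D.shape[0]
    if x.shape != (n,):
        raise ValueError("covariate length must match the distance matrix size")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; the marginal test is undefined")

    G = gower_center(D)
    trG = float(np.trace(G))

    def _ss_regression(xc):
        # with an intercept and one covariate, tr(HGH) reduces to the
        # quadratic form of the centred covariate (G is double-centred)
        xc = xc - xc.mean(axis=-1, keepdims=True)
        num = np.einsum("...i,ij,...j->...", xc, G, xc)
        return num / np.einsum("...i,...i->...", xc, xc)

    ss_reg = float(_ss_regression(x))
    ss_res = trG - ss_reg
    q = 1
    pseudo_f = (ss_reg / q) / (ss_res / (n - q - 1))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ss_perm = _ss_regression(x[perms])
    f_perm = (ss_perm / q) / ((trG - ss_perm) / (n - q - 1))
    count = int(np.sum(f_perm >= pseudo_f - 1e-12))
    p = (count + 1) / (n_perm + 1)

    return MarginalTestResult(
        covariate=name,
        pseudo_F=float(pseudo_f),
        prop_explained=float(ss_reg / trG),
        p_perm=float(p),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def run_marginal_suite(
    assemblage: dict,
    covariate_names=("grazing_area", "complexity_pc1", "depth"),
    n_perm: int = 9999,
    seed: int = 0,
    dummy_value: float = 1.0,
) -> pd.DataFrame:
    """Marginal DistLM tests for each response matrix and covariate.

    ``assemblage`` is the dict from :func:`reefscape.fish.build_assemblage`
    whose ``units`` table must carry the covariate columns. Tests run on the
    size-split abundance matrix and, when present, the pooled biomass matrix.
    """
    units = assemblage["units"]
    responses = {"abundance": assemblage["abundance"]}
    if "biomass" in assemblage:
        responses["biomass"] = assemblage["biomass"]
    rows = []
    for ri, (rname, mat) in enumerate(responses.items()):
        D = zero_adjusted_bray_curtis(mat, dummy_value=dummy_value)
        for ci, cov in enumerate(covariate_names):
            if cov not in units.columns:
                raise ValueError(f"units table lacks covariate column '{cov}'")
            res = distlm_marginal(
                D,
                units[cov].to_numpy(float),
                n_perm=n_perm,
                seed=seed + 1000 * ri + ci,
                name=cov,
            )
            rows.append(
                {
                    "response": rname,
                    "covariate": cov,
                    "pseudo_F": res.pseudo_F,
                    "prop_explained": res.prop_explained,
                    "p_perm": res.p_perm,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
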