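"""Group-conditional structure of the five AUD behaviors.

For the prone and resistant subgroups (and the whole cohort) this module
computes pairwise Spearman correlation matrices with p-values, a PCA of the
behaviors (eigendecomposition of the group's correlation matrix — behaviors
have incommensurable units, so the correlation rather than covariance matrix
is decomposed), and a binomial reference value: the fraction of animals
expected to meet >= k of m quantile criteria if the criteria were
independent, sum_{j>=k} C(m,j) q^j (1-q)^{m-j}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavioral_indices import BEHAVIOR_NAMES, BehaviorMatrix
from .errors import ScoringError


@dataclass
class PCAResult:
    loadings: pd.DataFrame        # behaviors x components, correlation scale
    explained_variance: np.ndarray  # fractions, summing to 1
    eigenvalues: np.ndarray


@dataclass
class GroupStructure:
    n: int
    spearman_r: pd.DataFrame | None
    spearman_p: pd.DataFrame | None
    pca: PCAResult | None

    def mean_offdiagonal_r(self) -> float:
        r = self.spearman_r.to_numpy()
        iu = np.triu_indices_from(r, k=1)
        return float(np.mean(r[iu]))


@dataclass
class StructureReport:
    groups: dict[str, GroupStructure]

    def to_dict(self) -> dict:
        out = {}
        for name, g in self.groups.items():
            entry: dict = {"n": g.n}
            if g.spearman_r is not None:
                entry["spearman_r"] = g.spearman_r.round(10).values.tolist()
                entry["spearman_p"] = g.spearman_p.round(10).values.tolist()
                entry["mean_offdiagonal_spearman_r"] = round(
                    g.mean_offdiagonal_r(), 10)
                entry["pca_explained_variance"] = [
                    round(float(v), 10) for v in g.pca.explained_variance]
                entry["pca_loadings"] = g.pca.loadings.round(10).values.tolist()
                entry["behavior_order"] = list(BEHAVIOR_NAMES)
            else:
                entry["note"] = "group too small for correlation/PCA (n < 4)"
            out[name] = entry
        return out


def _group_values(matrix: BehaviorMatrix, group_mask) -> np.ndarray:
    values = matrix.values
    if group_mask is not None:
        values = values[np.asarray(group_mask, bool)]
    return values


def spearman_matrix(matrix: BehaviorMatrix, group_mask=None,
                    exact: bool = False, n_resamples: int = 9999,
                    seed: int | None = None,
                    group_name: str = "group"
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman r (average ranks on ties) with two-sided p-values.

    By default p-values use the large-sample t approximation; ``exact=True``
    switches to permutation p-values (recommended for n < 10).
    """
    values = _group_values(matrix, group_mask)
    n = len(values)
    if n < 4:
        raise ScoringError(
            f"group {group_name!r} has {n} animals; need >= 4 for Spearman "
            "correlation"
        )
    names = list(matrix.behavior_names)
    p_dim = len(names)
    r = np.eye(p_dim)
    p = np.zeros((p_dim, p_dim))
    rng = np.random.default_rng(seed)
    for i in range(p_dim):
        for j in range(i + 1, p_dim):
            res = stats.spearmanr(values[:, i], values[:, j])
            rij, pij = float(res.statistic), float(res.pvalue)
            if exact:
                perm = stats.permutation_test(
                    (values[:, i], values[:, j]),
                    lambda x, y: stats.spearmanr(x, y).statistic,
                    permutation_type="pairings", n_resamples=n_resamples,
                    alternative="two-sided", rng=rng,
                )
                pij = float(perm.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=names, columns=names)
    pdf = pd.DataFrame(p, index=names, columns=names)
    return rdf, pdf


def pca_loadings(matrix: BehaviorMatrix, group_mask=None,
                 n_components: int | None = None,
                 group_name: str = "group") -> PCAResult:
    """PCA via eigendecomposition of the group's correlation matrix.

    Components are ordered by decreasing eigenvalue; each component's sign is
    oriented so its largest-magnitude loading is positive.  Loadings are on
    the correlation scale (eigenvector times sqrt(eigenvalue)); explained-
    variance fractions are eigenvalues divided by the number of behaviors.
    """
    values = _group_values(matrix, group_mask)
    n = len(values)
    if n < 4:
        raise ScoringError(
            f"group {group_name!r} has {n} animals; need >= 4 for PCA")
    sds = values.std(axis=0, ddof=1)
    zero = [name for name, s in zip(matrix.behavior_names, sds) if s == 0.0]
    if zero:
        raise ScoringError(
            f"zero-variance behavior column(s) within group {group_name!r}: "
            f"{zero}"
        )
    corr = np.corrcoef(values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for c in range(eigvec.shape[1]):
        top = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[top, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    k = n_components or len(matrix.behavior_names)
    loadings = eigvec[:, :k] * np.sqrt(eigval[np.newaxis, :k])
    df = pd.DataFrame(loadings, index=list(matrix.behavior_names),
                      columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(loadings=df,
                     explained_variance=eigval[:k] / len(matrix.behavior_names),
                     eigenvalues=eigval[:k])


def independence_null(q: float, m: int = 5, k: int = 2) -> float:
    """Expected fraction of animals meeting >= k of m criteria when the
    criteria are independent Bernoulli(q): the binomial upper tail."""
    if not 0.0 <= q <= 1.0:
        raise ScoringError("q must lie in [0, 1]")
    if not 0 <= k <= m:
        raise ScoringError("need 0 <= k <= m")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, m, q))


def structure_report(matrix: BehaviorMatrix, class_labels,
                     exact: bool = False, seed: int | None = None
                     ) -> StructureReport:
    """Spearman + PCA structure for the prone, resistant and pooled groups.

    Groups with fewer than 4 animals get an n-only entry with a warning
    rather than an error, so a pipeline run on an unlucky cohort still
    produces a report.
    """
    labels = np.asarray(class_labels)
    groups = {}
    for name, mask in (("prone", labels == "prone"),
                       ("resistant", labels == "resistant"),
                       ("all", np.ones(len(labels), bool))):
        n = int(mask.sum())
        if n < 4:
            warnings.warn(f"group {name!r} has only {n} animals; skipping "
                          "correlation/PCA", UserWarning, stacklevel=2)
            groups[name] = GroupStructure(n=n, spearman_r=None, spearman_p=None,
                                          pca=None)
            continue
        try:
            r, p = spearman_matrix(matrix, mask, exact=exact, seed=seed,
                                   group_name=name)
            pca = pca_loadings(matrix, mask, group_name=name)
        except ScoringError as err:  # e.g. a constant column inside a group
            warnings.warn(f"group {name!r}: {err}; skipping correlation/PCA",
                          UserWarning, stacklevel=2)
            groups[name] = GroupStructure(n=n, spearman_r=None,
                                          spearman_p=None, pca=None)
            continue
        groups[name] = GroupStructure(n=n, spearman_r=r, spearman_p=p, pca=pca)
    return StructureReport(groups=groups)
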