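"""Model/Results interface tying the pipeline together.

``ComorbidityTrajectories`` is constructed from person records (or the
cohort CSV files) and holds the analysis configuration; ``fit()`` runs
sequence construction, transition estimation, censoring-aware optimal
matching, classical MDS and Ward clustering, returning a
``ComorbidityTrajectoryResults`` object that carries the estimates and
exposes projection, association testing, dimension interpretation,
stability diagnostics and a text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import dissimilarity as _dissim
from . import embedding as _embedding
from . import sequences as _sequences

__all__ = ["ComorbidityTrajectories", "ComorbidityTrajectoryResults"]

#: categories treated as childhood-onset when orienting dimension 2
CHILDHOOD_CATEGORIES = ("F70", "F84", "F9")
#: category treated as substance use when orienting dimension 3
SUBSTANCE_CATEGORY = "F1"


class ComorbidityTrajectories:
    """Longitudinal comorbidity-trajectory model for a cohort.

    Parameters
    ----------
    persons : list of PersonRecord
        The cohort to analyze (typically the index cases).
    categories : sequence of str, optional
        Diagnosis category labels (default: the 8-category alphabet).
    increment : float
        Grid increment in years (1, 0.5 or 1/3).
    target_length : int
        Common sequence length after imputation (default 36 intervals).
    scheme, indel : str, float
        Substitution-cost scheme and indel cost of the optimal matching.
    """

    def __init__(self, persons, categories=None, increment: float = 1.0,
                 target_length: int = 36, scheme: str = "paper_overlap",
                 indel: float = 1.0):
        self.persons = list(persons)
        if not self.persons:
            raise ValueError("empty cohort")
        self.alphabet = _sequences.build_alphabet(
            categories or _sequences.DEFAULT_CATEGORIES)
        self.increment = float(increment)
        self.target_length = int(target_length)
        self.cost_model = _dissim.CostModel(scheme, indel)

    @classmethod
    def from_files(cls, directory, **kwargs) -> "ComorbidityTrajectories":
        from .synthetic import read_cohort

        return cls(read_cohort(directory), **kwargs)

    def fit(self, n_dims: int = 3, n_clusters="auto", k_max: int = 13,
            seed: int = 0) -> "ComorbidityTrajectoryResults":
        seqs = _sequences.build_sequences(self.persons, self.alphabet,
                                          self.increment, self.target_length)
        tmodel = _dissim.estimate_transitions(seqs, self.alphabet)
        D = _dissim.pairwise_matrix(seqs, self.cost_model, tmodel)
        emb = _embedding.classical_mds(D.values, n_dims)
        scores = self._orient(emb.scores)
        emb.scores = scores
        probe = _clustering.ward_cluster(scores, k=2, k_max=k_max)
        if n_clusters == "auto":
            k = _clustering.select_k(probe.r2_profile)
            k = max(k, 2)
        else:
            k = int(n_clusters)
        clusters = _clustering.ward_cluster(scores, k=k, k_max=k_max)
        return ComorbidityTrajectoryResults(self, seqs, tmodel, D, emb,
                                            clusters, seed)

    # -- score orientation against interpretable features ------------------
    def _features(self) -> pd.DataFrame:
        cats = self.alphabet.categories
        rows = []
        for p in self.persons:
            n_dx = len(p.events)
            child = any(c in p.events for c in CHILDHOOD_CATEGORIES
                        if c in cats)
            subst = SUBSTANCE_CATEGORY in p.events
            rows.append((n_dx, float(child), float(subst)))
        return pd.DataFrame(rows, columns=["count", "childhood", "substance"])

    def _orient(self, scores: np.ndarray) -> np.ndarray:
        feats = self._features()
        anchors = ["count", "childhood", "substance"]
        out = scores.copy()
        for j in range(scores.shape[1]):
            anchor = feats[anchors[j]] if j < len(anchors) else None
            if anchor is not None and anchor.std() > 0:
                r = np.corrcoef(out[:, j], anchor)[0, 1]
                if np.isfinite(r) and r < 0:
                    out[:, j] = -out[:, j]
        return out


@dataclass
class ComorbidityTrajectoryResults:
    """Fitted trajectory decomposition of a cohort."""

    model: ComorbidityTrajectories
    sequences: list
    transition_model: object
    dissimilarity: object  # DissimilarityMatrix
    mds: object  # EmbeddingResult
    clusters: object  # ClusterResult
    seed: int = 0

    @property
    def scores(self) -> np.ndarray:
        return self.mds.scores

    @property
    def labels(self) -> np.ndarray:
        return self.clusters.labels

    @property
    def n(self) -> int:
        return len(self.sequences)

    # -- downstream analyses ------------------------------------------------
    def project(self, persons) -> np.ndarray:
        """Project new individuals (e.g. a replication cohort) onto the
        fitted MDS dimensions via their OM distances to the cohort."""
        m = self.model
        new_seqs = _sequences.build_sequences(persons, m.alphabet,
                                              m.increment, m.target_length)
        d = _dissim.cross_matrix(new_seqs, self.sequences, m.cost_model,
                                 self.transition_model)
        return _embedding.project_new(d, self.mds)

    def associate(self, variables: pd.DataFrame, covariates=None,
                  threshold: float = 0.002) -> pd.DataFrame:
        from .associations import association_table

        return association_table(self.scores, variables, covariates,
                                 threshold)

    def interpret_dimensions(self) -> pd.DataFrame:
        feats = self.model._features()
        return _embedding.interpret_dimensions(self.scores, feats)

    def jackknife(self, max_leave_out: int = 100):
        return _embedding.jackknife_stability(self.dissimilarity.values,
                                              self.mds.k,
                                              max_leave_out=max_leave_out,
                                              seed=self.seed)

    def bootstrap_stability(self, n_resamples: int = 100):
        return _clustering.bootstrap_jaccard(self.scores, self.clusters.k,
                                             n_resamples=n_resamples,
                                             seed=self.seed)

    def surrogate_tree(self, max_depth: int = 4):
        """Decision-tree surrogate of the clustering on interpretable
        diagnosis features (indicators split before/after the index
        diagnosis plus ages at first diagnosis)."""
        feats = self._tree_features()
        return _clustering.surrogate_tree(feats, self.labels,
                                          max_depth=max_depth,
                                          seed=self.seed)

    def _tree_features(self) -> pd.DataFrame:
        cats = self.model.alphabet.categories
        rows = []
        for p in self.model.persons:
            rec = {}
            for c in cats:
                before = after = 0.0
                age = np.nan
                if c in p.events:
                    age = (p.events[c] - p.birth_date).days / 365.25
                    if p.scz_first_date and p.events[c] < p.scz_first_date:
                        before = 1.0
                    else:
                        after = 1.0
                rec[f"{c}_before"] = before
                rec[f"{c}_after"] = after
                rec[f"{c}_age"] = age
            rows.append(rec)
        df = pd.DataFrame(rows)
        ages = [c for c in df.columns if c.endswith("_age")]
        df[ages] = df[ages].fillna(99.0)  # sentinel: never diagnosed
        return df

    # -- reporting ----------------------------------------------------------
    def plot_r2_profile(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.clusters.r2_profile
        ax.plot(np.arange(1, len(prof) + 1), prof, marker="o")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel(r"$R^2$ (between-cluster / total score variance)")
        return ax

    def plot_scores(self, dims=(0, 1), ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a, b = dims
        for c in np.unique(self.labels):
            sel = self.labels == c
            ax.scatter(self.scores[sel, a], self.scores[sel, b], s=8,
                       label=f"cluster {c}")
        ax.set_xlabel(f"dimension {a + 1}")
        ax.set_ylabel(f"dimension {b + 1}")
        ax.legend()
        return ax

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        emb, cl = self.mds, self.clusters
        head = [
            ("n individuals", f"{self.n}"),
            ("grid increment (years)", f"{self.model.increment:g}"),
            ("target length", f"{self.model.target_length}"),
            ("cost scheme", self.model.cost_model.scheme),
            ("indel cost", f"{self.model.cost_model.indel_cost:g}"),
            ("MDS dimensions", f"{emb.k}"),
            ("variance explained (cum.)",
             f"{emb.cumulative_variance[-1]:.3f}"),
            ("negative eigenvalue mass", f"{emb.negative_mass:.4f}"),
            ("clusters k", f"{cl.k}"),
            ("cluster R^2", f"{cl.r2_profile[cl.k - 1]:.3f}"),
            ("cluster sizes", ", ".join(map(str, cl.sizes))),
        ]
        t1 = SimpleTable([[k, v] for k, v in head],
                         headers=["", ""],
                         title="Comorbidity trajectory decomposition")
        per_dim = [[f"dim {j+1}", f"{emb.eigenvalues[j]:.4g}",
                    f"{emb.variance_explained[j]:.3f}",
                    f"{emb.cumulative_variance[j]:.3f}"]
                   for j in range(emb.k)]
        t2 = SimpleTable(per_dim,
                         headers=["", "eigenvalue", "var. fraction",
                                  "cumulative"])
        return str(t1) + "\n" + str(t2)
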