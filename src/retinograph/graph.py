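"""Image-level population graph from demographic similarity.

Nodes are fundus images carrying their biomarker vectors; an undirected edge
links two images when their subjects match on gender and/or are within five
years of age.  The similarity score is

    score = [same gender] + [|age_i − age_j| < 5]   ∈ {0, 1, 2}

and pairs scoring 0 are not connected.  Two images of the same subject
trivially satisfy both criteria and are linked with weight 2 (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["similarity_score", "build_graph", "PopulationGraph", "AGE_WINDOW_YEARS"]

AGE_WINDOW_YEARS = 5.0


def _age_gender(subject) -> tuple[float, str]:
    if hasattr(subject, "age"):
        age, gender = subject.age, subject.gender
    else:
        age, gender = subject["age"], subject["gender"]
    if age is None or (isinstance(age, float) and np.isnan(age)):
        raise ValueError("missing age")
    if gender not in ("male", "female"):
        raise ValueError(f"missing or invalid gender: {gender!r}")
    return float(age), gender


def similarity_score(subject_i, subject_j) -> int:
    """Demographic similarity in {0, 1, 2}: one point for identical gender,
    one for an age difference strictly below five years.  Symmetric."""
    age_i, gender_i = _age_gender(subject_i)
    age_j, gender_j = _age_gender(subject_j)
    return int(gender_i == gender_j) + int(abs(age_i - age_j) < AGE_WINDOW_YEARS)


@dataclass
class PopulationGraph:
    """Weighted image-level graph plus aligned node features."""

    graph: nx.Graph
    image_ids: list
    X: np.ndarray                  # (n_images, n_features), schema order
    feature_names: list
    subject_of: dict               # image_id -> subject_id

    @property
    def n_nodes(self) -> int:
        return len(self.image_ids)

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Sparse adjacency in ``image_ids`` order (binary unless weighted)."""
        a = nx.to_scipy_sparse_array(
            self.graph, nodelist=self.image_ids,
            weight="weight" if weighted else None, format="csr",
        )
        return sp.csr_matrix(a)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"src": u, "dst": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["src", "dst", "weight"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_graph(
    cohort: pd.DataFrame,
    feature_table: pd.DataFrame,
    feature_names: list | None = None,
    link_same_subject: bool = True,
) -> PopulationGraph:
    """Build the population graph from a cohort and an image feature table.

    ``cohort`` needs one row per subject with ``subject_id``, ``age``,
    ``gender``; ``feature_table`` one row per image with ``image_id``,
    ``subject_id`` and the feature columns.  Edges between images of
    different subjects carry their subjects' similarity score (pairs scoring
    0 are left unconnected); images of one subject are linked with weight 2
    unless ``link_same_subject`` is false.
    """
    if feature_table["image_id"].duplicated().any():
        dups = feature_table.loc[feature_table["image_id"].duplicated(), "image_id"]
        raise ValueError(f"duplicate image ids: {sorted(set(dups))}")
    if feature_names is None:
        feature_names = [
            c for c in feature_table.columns
            if c not in ("image_id", "subject_id", "eye", "label")
        ]
    subjects = cohort.set_index("subject_id")
    missing = set(feature_table["subject_id"]) - set(subjects.index)
    if missing:
        raise ValueError(f"images reference unknown subjects: {sorted(missing)}")

    image_ids = list(feature_table["image_id"])
    subject_of = dict(zip(feature_table["image_id"], feature_table["subject_id"]))
    ages = subjects.loc[feature_table["subject_id"], "age"].to_numpy(float)
    genders = subjects.loc[feature_table["subject_id"], "gender"].to_numpy()
    if np.any(pd.isna(ages)):
        raise ValueError("missing ages in cohort")

    g = nx.Graph()
    g.add_nodes_from(image_ids)
    n = len(image_ids)
    same_gender = genders[:, None] == genders[None, :]
    close_age = np.abs(ages[:, None] - ages[None, :]) < AGE_WINDOW_YEARS
    score = same_gender.astype(int) + close_age.astype(int)
    subj = feature_table["subject_id"].to_numpy()
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if subj[i] == subj[j]:
            if link_same_subject:
                g.add_edge(image_ids[i], image_ids[j], weight=2)
            continue
        s = score[i, j]
        if s > 0:
            g.add_edge(image_ids[i], image_ids[j], weight=int(s))

    X = feature_table[feature_names].to_numpy(float)
    return PopulationGraph(
        graph=g, image_ids=image_ids, X=X,
        feature_names=list(feature_names), subject_of=subject_of,
    )
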