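"""Cross-session cell identification by ROI centroid proximity.

Candidate matches pair each cell of session A with its nearest cell in
session B; a candidate is accepted when the Euclidean centroid distance is
strictly below the threshold (default 6.5 um).  One-to-one matching is
enforced greedily in ascending distance order — a B cell claimed by a closer
A cell is unavailable to later candidates — with exact distance ties broken
by the lower A index.  Coordinates are assumed pre-registered into a common
micrometre frame; no image registration is performed here.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import stats

RESPONSIVE = ("excited", "inhibited")


def match_cells(centroids_a, centroids_b, max_dist: float = 6.5) -> pd.DataFrame:
    """One-to-one nearest-neighbour matches with distance < max_dist.

    Returns a DataFrame with columns ``neuron_id_a, neuron_id_b, distance``,
    sorted by ascending distance.  Empty centroid tables give an empty match
    list.
    """
    a = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    b = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    cols = ["neuron_id_a", "neuron_id_b", "distance"]
    if a.size == 0 or b.size == 0:
        return pd.DataFrame(columns=cols)
    d = cdist(a, b)
    nearest = d.argmin(axis=1)  # ties resolved to the lower B index
    dist = d[np.arange(len(a)), nearest]
    order = np.lexsort((np.arange(len(a)), dist))  # ascending distance, then A index
    taken = np.zeros(len(b), dtype=bool)
    rows = []
    for ia in order:
        ib = nearest[ia]
        if dist[ia] < max_dist and not taken[ib]:
            taken[ib] = True
            rows.append((int(ia), int(ib), float(dist[ia])))
    return pd.DataFrame(rows, columns=cols)


def cross_session_contingency(matches: pd.DataFrame, labels_a, labels_b,
                              collapse: str = "responsive"):
    """Label association of matched neurons across two sessions.

    ``labels_a`` / ``labels_b`` map neuron index to its response label in
    each session.  With ``collapse="responsive"`` the labels are collapsed to
    responsive (excited or inhibited) vs stable and tested with a two-sided
    Fisher 2x2 exact test.  Neurons excluded in either session are dropped.
    Returns ``(table, result)``; both are None when no matched neuron carries
    labels in both sessions.
    """
    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    la = labels_a[matches["neuron_id_a"].to_numpy(dtype=int)] if len(matches) else np.array([])
    lb = labels_b[matches["neuron_id_b"].to_numpy(dtype=int)] if len(matches) else np.array([])
    ok = np.array([x != "excluded" and y != "excluded" for x, y in zip(la, lb)],
                  dtype=bool) if len(matches) else np.array([], dtype=bool)
    if ok.sum() < 1:
        return None, None
    la, lb = la[ok], lb[ok]
    if collapse != "responsive":
        raise ValueError(f"unknown collapse mode {collapse!r}")
    ra = np.isin(la, RESPONSIVE)
    rb = np.isin(lb, RESPONSIVE)
    table = pd.DataFrame(
        [[int((ra & rb).sum()), int((ra & ~rb).sum())],
         [int((~ra & rb).sum()), int((~ra & ~rb).sum())]],
        index=["a_responsive", "a_stable"], columns=["b_responsive", "b_stable"])
    result = stats.fisher_exact_2x2(table.to_numpy())
    return table, result
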