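"""Independent brute-force re-implementations used only as test oracles.

These deliberately avoid the package's pruning/eigendecomposition code
path: transition matrices come from scipy's dense matrix exponential and
site likelihoods from explicit enumeration of every internal-node state
assignment.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.linalg import expm

from selscreen.codon import CODON_INDEX, N_CODONS, rate_matrix
from selscreen.io import CodonAlignment, LabeledTree, ProteinAlignment

CLASS_OMEGA_KEYS = [("omega0", "omega0"), ("one", "one"), ("omega0", "omega2"), ("one", "omega2")]


def brute_force_loglik(aln: CodonAlignment, tree: LabeledTree, params, pi: np.ndarray) -> float:
    """Model A mixture log-likelihood by full ancestral-state enumeration."""
    omegas = {"omega0": params.omega0, "one": 1.0, "omega2": params.omega2}
    props = params.class_proportions()
    # shared time scale: background-mixture expected flux
    q_unnorm = {k: rate_matrix(params.kappa, w, pi, normalize=False) for k, w in omegas.items()}
    rate = {k: -(pi * np.diag(q)).sum() for k, q in q_unnorm.items()}
    w0 = props[0] + props[2]
    rho = w0 * rate["omega0"] + (1 - w0) * rate["one"]

    fg_node = tree.foreground_node()
    internals = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.tree.leaf_node_iter()]
    node_index = {id(nd): k for k, nd in enumerate(internals)}
    leaf_row = {nd.taxon.label: aln.taxa.index(nd.taxon.label) for nd in leaves}

    # per-class transition matrices per edge
    def edge_p(child, key):
        t = (child.edge.length or 0.0) * params.tree_scale / rho
        return expm(q_unnorm[key] * t)

    total = 0.0
    for col in range(aln.n_codons):
        observed = {t: CODON_INDEX[aln.codon(t, col + 1)] for t in aln.taxa}
        site_lik = 0.0
        for prop, (bg_key, fg_key) in zip(props, CLASS_OMEGA_KEYS):
            if prop == 0.0:
                continue
            p_of = {}
            for nd in tree.tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                key = fg_key if nd is fg_node else bg_key
                p_of[id(nd)] = edge_p(nd, key)
            class_lik = 0.0
            for assign in product(range(N_CODONS), repeat=len(internals)):
                prob = pi[assign[node_index[id(tree.tree.seed_node)]]]
                for nd in tree.tree.preorder_node_iter():
                    if nd.parent_node is None:
                        continue
                    parent_state = assign[node_index[id(nd.parent_node)]]
                    child_state = (
                        observed[nd.taxon.label] if nd.is_leaf() else assign[node_index[id(nd)]]
                    )
                    prob *= p_of[id(nd)][parent_state, child_state]
                    if prob == 0.0:
                        break
                class_lik += prob
            site_lik += prop * class_lik
        total += np.log(site_lik)
    return float(total)


def naive_sp_score(aln: ProteinAlignment, focal: str, column: int, window: int = 15):
    """Straight-line re-implementation of SP general/individual scoring."""
    focal_seq = aln.sequence_of(focal)
    n_cols = len(focal_seq)

    def stream(direction):
        cols, count = [], 0
        rng = range(column - 2, -1, -1) if direction == "up" else range(column, n_cols)
        for c0 in rng:
            cols.append(c0)
            if focal_seq[c0] != "-":
                count += 1
                if count == window:
                    break
        while cols and focal_seq[cols[-1]] == "-":
            cols.pop()
        return cols, count

    up_cols, n_up = stream("up")
    down_cols, n_down = stream("down")

    def penalty(i, j, cols, s):
        score = 0.0
        for c0 in cols:
            a, b = aln.sequences[i][c0], aln.sequences[j][c0]
            if a == "-" and b == "-":
                continue
            if a == "-" or b == "-":
                score -= 2 * s
            elif a != b:
                score -= s
        return score

    s_up = window / n_up if n_up else 0.0
    s_down = window / n_down if n_down else 0.0
    n_seq = aln.n_taxa
    fi = aln.taxa.index(focal)

    def pair_total(i, j):
        return (penalty(i, j, up_cols, s_up) if n_up else 0.0) + (penalty(i, j, down_cols, s_down) if n_down else 0.0)

    general = sum(pair_total(i, j) for i, j in combinations(range(n_seq), 2)) / n_seq
    individual = sum(pair_total(fi, j) for j in range(n_seq) if j != fi)
    return general, individual
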