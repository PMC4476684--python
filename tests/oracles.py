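"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (explicit
row scans, exact rational arithmetic, O(n^2) pair counting) and never
calls the library's own scoring or search code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from decisionpath.core import MISSING


def dirichlet_multinomial_log_marginal(counts, alpha: Fraction) -> float:
    """Exact log marginal of one sample via the sequential chain rule.

    P(x_1..x_N) = prod_i (alpha_{k_i} + n^{<i}_{k_i}) / (K alpha + i - 1),
    evaluated in exact rational arithmetic and logged at the end.
    """
    seen = [0] * len(counts)
    prob = Fraction(1)
    total_alpha = alpha * len(counts)
    i = 0
    for k, c in enumerate(counts):
        for _ in range(int(c)):
            prob *= (alpha + seen[k]) / (total_alpha + i)
            seen[k] += 1
            i += 1
    return math.log(prob)


def two_sample_log_marginal(counts_in, counts_out, alpha: Fraction) -> float:
    return (dirichlet_multinomial_log_marginal(counts_in, alpha)
            + dirichlet_multinomial_log_marginal(counts_out, alpha))


def pair_counting_auc(scores, labels) -> float:
    """O(n_pos * n_neg) concordant/tied pair count."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    num = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(pos) * len(neg))


def entropy2(counts) -> float:
    n = sum(counts)
    if n == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            h -= (c / n) * math.log2(c / n)
    return h


def _counts(rows, k):
    out = [0] * k
    for y in rows:
        out[y] += 1
    return out


def _loocv_preds(rows_y, pos, pess=1.0, k=2):
    """Materialize each leave-one-out table explicitly."""
    preds = []
    for i in range(len(rows_y)):
        rest = rows_y[:i] + rows_y[i + 1:]
        c = _counts(rest, k)
        preds.append((pess / k + c[pos]) / (pess + len(rest)))
    return preds


def candidate_scores(X, y, rows, cands, person, criterion, pess=1.0,
                     positive_index=1):
    """Oracle split scores for every viable candidate at one search step.

    Returns [(column, score), ...] in candidate order; candidates whose
    matching part would be empty are omitted (they would strand the
    search).  Scores are computed from first principles: the Bayesian
    score in exact rational arithmetic, information gain and the LOOCV
    AUC by explicit enumeration.
    """
    k = max(max(y) + 1, 2) if y else 2
    out = []
    for j in cands:
        inside = [i for i in rows if X[i][j] == person[j]]
        if not inside:
            continue
        outside = [i for i in rows if X[i][j] != person[j]]
        cin = _counts([y[i] for i in inside], k)
        cout = _counts([y[i] for i in outside], k)
        if criterion == "bay":
            score = two_sample_log_marginal(cin, cout, Fraction(1, k))
        elif criterion == "ig":
            cd = _counts([y[i] for i in rows], k)
            n = len(rows)
            score = (entropy2(cd)
                     - len(inside) / n * entropy2(cin)
                     - len(outside) / n * entropy2(cout))
        else:  # auc
            preds, labels = [], []
            for part in (inside, outside):
                if not part:
                    continue
                ys = [y[i] for i in part]
                preds += _loocv_preds(ys, positive_index, pess, k)
                labels += [yy == positive_index for yy in ys]
            if any(labels) and not all(labels):
                score = pair_counting_auc(preds, labels)
            else:
                score = 0.5
        out.append((j, score))
    return out


def brute_force_greedy(X, y, person, criterion, pess=1.0, positive_index=1,
                       tie_tol=1e-9):
    """Independent greedy growth + pruning with plain Python loops.

    X: list of rows (lists of int codes, -1 missing); y: list of int;
    person: list of int codes (-1 missing).  Returns (scores, pruned
    conjunct index list, ambiguous) where conjuncts are (column, code)
    pairs and ``ambiguous`` flags any step whose top two candidate
    scores were within ``tie_tol`` — there the greedy selection (hence
    everything after it) is not uniquely defined up to rounding.
    """
    rows = list(range(len(y)))
    cands = [j for j in range(len(person)) if person[j] != MISSING]
    steps = []  # (j, score)
    ambiguous = False
    while cands and rows:
        if len({y[i] for i in rows}) == 1:
            break
        cs = candidate_scores(X, y, rows, cands, person, criterion,
                              pess, positive_index)
        if not cs:
            break
        best_j, best_s = cs[0]
        for j, s in cs[1:]:
            if s > best_s:
                best_j, best_s = j, s
        if sum(1 for _, s in cs if s >= best_s - tie_tol) > 1:
            ambiguous = True
        steps.append((best_j, best_s))
        rows = [i for i in rows if X[i][best_j] == person[best_j]]
        cands.remove(best_j)
    if not steps:
        return [], [], ambiguous
    scores = [s for _, s in steps]
    best_idx = scores.index(max(scores))
    return scores, [(j, person[j]) for j, _ in steps[: best_idx + 1]], ambiguous


def verify_greedy_trace(X, y, person, criterion, impl_steps, pruned_len,
                        tol=1e-9, pess=1.0, positive_index=1):
    """Replay-validate an implementation trace against the oracle scorer.

    At every step the chosen feature must (a) be a viable candidate,
    (b) carry the oracle's score for that feature within ``tol``, and
    (c) achieve the oracle's maximum within ``tol``.  Afterwards one of
    the stopping conditions must genuinely hold, and the pruned length
    must be the first argmax of the recorded scores.
    """
    rows = list(range(len(y)))
    cands = [j for j in range(len(person)) if person[j] != MISSING]
    for j, sc in impl_steps:
        cs = dict(candidate_scores(X, y, rows, cands, person, criterion,
                                   pess, positive_index))
        assert j in cs, f"chosen column {j} not a viable candidate"
        assert abs(cs[j] - sc) <= tol, f"score mismatch at column {j}"
        assert cs[j] >= max(cs.values()) - tol, f"non-greedy pick {j}"
        rows = [i for i in rows if X[i][j] == person[j]]
        cands.remove(j)
    if cands and rows and len({y[i] for i in rows}) > 1:
        leftover = candidate_scores(X, y, rows, cands, person, criterion,
                                    pess, positive_index)
        assert not leftover, "search stopped with viable candidates left"
    scores = [s for _, s in impl_steps]
    if scores:
        m = max(scores)
        assert pruned_len == scores.index(m) + 1, "pruning not at first argmax"
    else:
        assert pruned_len == 0
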