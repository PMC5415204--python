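"""Pairwise maximum-entropy (Potts) modelling of aligned protein families.

A sequence σ is scored by E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j),
interpreted as a log-likelihood up to a constant. Fields and couplings are
estimated by weighted, L2-regularized pseudolikelihood maximization; the
independent-site special case (all J = 0, fields = log of smoothed column
frequencies) is the conservation baseline. A mutant's effect is the
wild-type-minus-mutant energy difference with all other positions fixed to
the query sequence — positive scores mean the mutation is disfavoured by
the family (more damaging). Energy *differences* are gauge-invariant;
models are reported in the zero-sum gauge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .msa import Msa, SequenceWeights
from .variants import VariantKey

__all__ = [
    "PottsModel",
    "MutationScore",
    "PottsFitError",
    "fit_independent",
    "fit_potts",
    "score_variant",
    "score_all_substitutions",
    "sample_msa",
]


class PottsFitError(RuntimeError):
    """Pseudolikelihood optimisation failed to converge."""


@dataclass(frozen=True)
class MutationScore:
    key: VariantKey
    delta_loglik: float  # wild-type minus mutant energy; larger = more damaging


@dataclass
class PottsModel:
    """Site fields ``h`` (L, q) and symmetric couplings ``J`` (L, L, q, q).

    ``J[i, j, a, b]`` couples state ``a`` at column ``i`` with state ``b``
    at column ``j``; diagonal blocks are zero and ``J[i,j] == J[j,i].T``.
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: str
    gauge: str = "none"
    lambda_h: float = 0.0
    lambda_J: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} inconsistent with h shape {self.h.shape}")
        if len(self.alphabet) != q:
            raise ValueError("alphabet size does not match state dimension")

    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def n_states(self) -> int:
        return self.h.shape[1]

    def energy(self, seq) -> float:
        """E(σ): field terms plus each coupling counted once (i < j)."""
        s = np.asarray(seq, dtype=np.int64)
        if s.shape != (self.length,):
            raise ValueError("sequence length does not match the model")
        e = float(self.h[np.arange(self.length), s].sum())
        for i in range(self.length):
            for j in range(i + 1, self.length):
                e += float(self.J[i, j, s[i], s[j]])
        return e

    def to_zero_sum(self) -> "PottsModel":
        """Re-gauge so fields and coupling rows/columns sum to zero.

        Sequence-energy differences are unchanged; only the parameter
        decomposition moves between h and J.
        """
        L, q = self.h.shape
        J = self.J.copy()
        h = self.h.copy()
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                block = J[i, j]
                row_mean = block.mean(axis=1, keepdims=True)  # over b
                col_mean = block.mean(axis=0, keepdims=True)  # over a
                total = block.mean()
                J[i, j] = block - row_mean - col_mean + total
                # the field at i absorbs the per-state row means of every partner block
                h[i] += row_mean.ravel() - total
        h -= h.mean(axis=1, keepdims=True)
        return PottsModel(h, J, self.alphabet, gauge="zero-sum",
                          lambda_h=self.lambda_h, lambda_J=self.lambda_J, meta=dict(self.meta))

    def coupling_norms(self) -> np.ndarray:
        """(L, L) Frobenius norms of the zero-sum-gauge coupling blocks."""
        zs = self if self.gauge == "zero-sum" else self.to_zero_sum()
        return np.sqrt((zs.J ** 2).sum(axis=(2, 3)))

    # --- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "alphabet": self.alphabet,
            "gauge": self.gauge,
            "lambda_h": self.lambda_h,
            "lambda_J": self.lambda_J,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PottsModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            h=np.array(payload["h"]),
            J=np.array(payload["J"]),
            alphabet=payload["alphabet"],
            gauge=payload.get("gauge", "none"),
            lambda_h=payload.get("lambda_h", 0.0),
            lambda_J=payload.get("lambda_J", 0.0),
            meta=payload.get("meta", {}),
        )


def _one_hot(matrix: np.ndarray, q: int) -> np.ndarray:
    n, L = matrix.shape
    X = np.zeros((n, L, q), dtype=float)
    X[np.arange(n)[:, None], np.arange(L)[None, :], matrix] = 1.0
    return X


def fit_independent(
    msa: Msa, weights: SequenceWeights, pseudocount: float = 0.01, gauge_fix: bool = True
) -> PottsModel:
    """Conservation baseline: fields = log smoothed weighted frequencies, J = 0.

    Frequencies are mixed with the uniform distribution,
    f̂ = (1 − λ)·f + λ/q, so every state has positive probability for λ > 0.
    ``gauge_fix=False`` keeps the raw log-frequency fields (mutation scores
    are identical either way — they are within-column differences).
    """
    if not 0.0 <= pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in [0, 1]")
    X = _one_hot(msa.matrix, msa.n_states)
    w = np.asarray(weights.weights, dtype=float)
    if w.shape[0] != msa.n_sequences:
        raise ValueError("weights do not match the alignment")
    total = w.sum()
    if total <= 0:
        raise ValueError("total sequence weight is zero")
    freq = np.tensordot(w, X, axes=(0, 0)) / total  # (L, q)
    f_hat = (1.0 - pseudocount) * freq + pseudocount / msa.n_states
    with np.errstate(divide="ignore"):
        h = np.log(f_hat)
    L, q = h.shape
    model = PottsModel(h, np.zeros((L, L, q, q)), msa.alphabet,
                       lambda_h=pseudocount, meta={"family": "independent"})
    return model.to_zero_sum() if gauge_fix else model


def _pl_objective(theta, Xf, x_idx, w, L, q, lambda_h, lambda_J, iu, ju):
    """Weighted negative log-pseudolikelihood with L2 penalty, plus gradient.

    The likelihood term is normalized by the total sequence weight so the
    objective (and the convergence tolerance and regularization strengths)
    do not scale with alignment depth.
    """
    n = Xf.shape[0]
    n_pairs = iu.size
    h = theta[: L * q].reshape(L, q)
    Jb = theta[L * q :].reshape(n_pairs, q, q)

    # assemble the full (Lq, Lq) symmetric coupling matrix, zero diagonal blocks
    Jmat = np.zeros((L * q, L * q))
    for p in range(n_pairs):
        i, j = iu[p], ju[p]
        Jmat[i * q : (i + 1) * q, j * q : (j + 1) * q] = Jb[p]
        Jmat[j * q : (j + 1) * q, i * q : (i + 1) * q] = Jb[p].T

    W = float(w.sum())
    logits = (Xf @ Jmat).reshape(n, L, q) + h[None, :, :]
    m = logits.max(axis=2, keepdims=True)
    expl = np.exp(logits - m)
    Z = expl.sum(axis=2, keepdims=True)
    logZ = (m + np.log(Z)).squeeze(2)  # (n, L)
    picked = np.take_along_axis(logits, x_idx[:, :, None], axis=2).squeeze(2)
    nll = -float(np.sum(w[:, None] * (picked - logZ))) / W

    P = expl / Z  # (n, L, q) conditional probabilities
    D = P.copy()
    D[np.arange(n)[:, None], np.arange(L)[None, :], x_idx] -= 1.0
    D *= w[:, None, None] / W
    grad_h = D.sum(axis=0)

    Df = D.reshape(n, L * q)
    G = Df.T @ Xf  # G[ia, jb] = dNLL/dJfull[i,a,j,b] (asymmetric)
    grad_Jb = np.empty_like(Jb)
    for p in range(n_pairs):
        i, j = iu[p], ju[p]
        Gij = G[i * q : (i + 1) * q, j * q : (j + 1) * q]
        Gji = G[j * q : (j + 1) * q, i * q : (i + 1) * q]
        grad_Jb[p] = Gij + Gji.T

    obj = nll + lambda_h * float((h ** 2).sum()) + lambda_J * float((Jb ** 2).sum())
    grad_h = grad_h + 2.0 * lambda_h * h
    grad_Jb = grad_Jb + 2.0 * lambda_J * Jb
    return obj, np.concatenate([grad_h.ravel(), grad_Jb.ravel()])


def fit_potts(
    msa: Msa,
    weights: SequenceWeights,
    lambda_h: float = 0.01,
    lambda_J: float = 0.01,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> PottsModel:
    """Fit fields and couplings by L2-regularized pseudolikelihood.

    The objective is the weighted product over sites of conditional
    likelihoods p(σ_i | σ_−i), normalized by the total sequence weight and
    maximized with L-BFGS using an analytic gradient; couplings are
    parameterized symmetrically (one L2-penalized block per column pair).
    The fitted model is returned in the zero-sum gauge. Deterministic given
    the data and settings.
    """
    L, q = msa.length, msa.n_states
    if L < 2:
        raise ValueError("need at least 2 columns to fit couplings")
    if weights.m_eff <= 1:
        raise ValueError("effective sequence count must exceed 1")

    Xf = _one_hot(msa.matrix, q).reshape(msa.n_sequences, L * q)
    x_idx = msa.matrix
    w = np.asarray(weights.weights, dtype=float)
    iu, ju = np.triu_indices(L, k=1)
    theta0 = np.zeros(L * q + iu.size * q * q)

    res = minimize(
        _pl_objective,
        theta0,
        args=(Xf, x_idx, w, L, q, lambda_h, lambda_J, iu, ju),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > 10 * tol and not res.success:
        raise PottsFitError(
            f"pseudolikelihood fit did not converge in {max_iter} iterations "
            f"(max |gradient| = {grad_norm:.3g})"
        )

    h = res.x[: L * q].reshape(L, q)
    Jb = res.x[L * q :].reshape(iu.size, q, q)
    J = np.zeros((L, L, q, q))
    for p in range(iu.size):
        i, j = iu[p], ju[p]
        J[i, j] = Jb[p]
        J[j, i] = Jb[p].T
    model = PottsModel(h, J, msa.alphabet, lambda_h=lambda_h, lambda_J=lambda_J,
                       meta={"family": "potts", "grad_norm": grad_norm,
                             "m_eff": weights.m_eff, "n_iter": int(res.nit)})
    return model.to_zero_sum()


def score_variant(model: PottsModel, msa: Msa, key: VariantKey) -> MutationScore | None:
    """Wild-type-minus-mutant energy with the rest of the query fixed.

    Returns ``None`` ("no prediction") when the position is outside the
    alignment's mapped range; raises if the stated wild-type residue does
    not match the query. Gauge-invariant.
    """
    col = msa.column_for_position(key.position)
    if col is None:
        return None
    query = msa.query_row()
    alphabet = model.alphabet
    wt_state = alphabet.index(key.wt_aa) if key.wt_aa in alphabet else None
    mut_state = alphabet.index(key.mut_aa) if key.mut_aa in alphabet else None
    if wt_state is None or mut_state is None:
        raise ValueError(f"residues of {key} not in the model alphabet")
    if query[col] != wt_state:
        raise ValueError(
            f"wild-type mismatch at position {key.position}: query has "
            f"{alphabet[query[col]]}, variant says {key.wt_aa}"
        )
    delta = float(model.h[col, wt_state] - model.h[col, mut_state])
    for j in range(model.length):
        if j == col:
            continue
        delta += float(model.J[col, j, wt_state, query[j]] - model.J[col, j, mut_state, query[j]])
    return MutationScore(key=key, delta_loglik=delta)


def score_all_substitutions(model: PottsModel, msa: Msa) -> list[MutationScore]:
    """Scores for every substitution at every mapped, non-gap query position."""
    from .variants import AMINO_ACIDS

    scores = []
    query = msa.query_row()
    for col, pos in sorted(msa.column_map.items()):
        wt = msa.alphabet[query[col]]
        if wt not in AMINO_ACIDS:
            continue
        for mut in AMINO_ACIDS:
            if mut == wt or mut not in model.alphabet:
                continue
            s = score_variant(model, msa, VariantKey(wt, pos, mut))
            if s is not None:
                scores.append(s)
    return scores


def sample_msa(
    model: PottsModel,
    n_sequences: int,
    burn_in: int = 500,
    thin: int = 20,
    seed: int | None = None,
    query_index: int = 0,
) -> Msa:
    """Draw an alignment from the model by single-chain Gibbs sampling.

    One sweep updates every column once; ``burn_in`` sweeps are discarded
    and one sequence is emitted every ``thin`` sweeps thereafter. Strong
    couplings slow single-site Gibbs mixing considerably (state pairs must
    cross an energy barrier one column at a time), so the defaults are
    deliberately conservative. Seeded and reproducible.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be positive")
    rng = np.random.default_rng(seed)
    L, q = model.length, model.n_states
    # flattened per-site coupling rows: row[i] is (q, L*q)
    Jrows = [model.J[i].transpose(1, 0, 2).reshape(q, L * q) for i in range(L)]
    state = rng.integers(0, q, size=L)
    offsets = np.arange(L) * q

    def sweep() -> None:
        for i in range(L):
            logits = model.h[i] + Jrows[i][:, offsets + state].sum(axis=1) - model.J[i, i, :, state[i]]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            state[i] = rng.choice(q, p=p)

    for _ in range(burn_in):
        sweep()
    rows = np.empty((n_sequences, L), dtype=np.int64)
    for s in range(n_sequences):
        for _ in range(thin):
            sweep()
        rows[s] = state
    return Msa(rows, alphabet=model.alphabet, query_index=min(query_index, n_sequences - 1))
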