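"""Supervised three-population ancestry with bootstrap standard errors.

Each focal bird is analysed one at a time against fixed reference
panels (ABDU / WMA / GFM), avoiding the confounding that joint
estimation suffers when the focal set is a web of close relatives.  The
ancestry vector q maximises the standard admixture binomial likelihood

    l(q) = sum_i [ x_i log(sum_k q_k f_ik) + (2 - x_i) log(sum_k q_k (1 - f_ik)) ]

over the simplex by EM, with panel allele frequencies f held fixed.
Standard errors come from resampling sites with replacement; a sample is
called genetically pure when its best assignment plus its standard error
reaches the purity threshold (default 98%).  A father's ancestry is
recoverable by subtraction: q_father = 2 q_offspring - q_mother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix

log = logging.getLogger(__name__)

POPS = ("ABDU", "WMA", "GFM")

EM_TOL = 1e-4
EM_MAX_ITER = 2000


@dataclass
class QVector:
    """Ancestry proportions on the simplex, with bootstrap SEs."""

    q: np.ndarray                      # (K,), sums to 1
    se: np.ndarray | None = None       # (K,) bootstrap standard errors
    n_sites: int = 0
    loglik: float = np.nan
    converged: bool = True
    loglik_path: list[float] = field(default_factory=list)

    def component(self, pop: str) -> float:
        return float(self.q[POPS.index(pop)])


@dataclass
class SpeciesCall:
    """Species/hybrid label derived from a QVector."""

    label: str
    pure: bool


def estimate_ref_freqs(M: GenotypeMatrix,
                       labels: dict[str, str]) -> np.ndarray:
    """Per-population alt-allele frequencies from labelled reference panels.

    Frequencies are clamped to ``[1/(2 n_k + 1), 1 - 1/(2 n_k + 1)]`` so
    that no site is exactly fixed (which would put log(0) into the
    likelihood).  Returns an ``(n_sites, K)`` array in ABDU, WMA, GFM
    column order.
    """
    cols = []
    for pop in POPS:
        ids = [s for s, p in labels.items() if p == pop]
        if len(ids) < 2:
            raise ValueError(f"reference population {pop} needs >= 2 samples")
        sub = M.subset_samples(ids)
        called = ~np.isnan(sub.dosages)
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nansum(sub.dosages, axis=1) / (2.0 * n_called)
        f = np.where(n_called > 0, f, 0.5)
        eps = 1.0 / (2.0 * len(ids) + 1.0)
        cols.append(np.clip(f, eps, 1.0 - eps))
    return np.column_stack(cols)


def _em_batch(X: np.ndarray, F: np.ndarray,
              tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
              track: bool = False, site_weights: np.ndarray | None = None):
    """Run the supervised-admixture EM on a batch of dosage vectors.

    ``X`` is (B, S) with NaN for missing; ``F`` is (S, K).
    ``site_weights`` (B, S), when given, multiplies each site's
    contribution (a multinomial weight vector is equivalent to
    resampling sites with replacement).  Returns (q (B, K), loglik (B,),
    converged (B,), paths) where ``paths`` is a list of per-iteration
    log-likelihood lists when ``track``.
    """
    B, S = X.shape
    K = F.shape[1]
    W = np.nan_to_num(X, nan=0.0)
    C = (~np.isnan(X)).astype(float)      # called mask
    if site_weights is not None:
        C = C * site_weights
    alt = W * C                           # alt-allele counts
    ref = (2.0 - W) * C                   # ref-allele counts
    n_used = C.sum(axis=1)

    q = np.full((B, K), 1.0 / K)
    ll_prev = np.full(B, -np.inf)
    converged = np.zeros(B, dtype=bool)
    paths: list[list[float]] = [[] for _ in range(B)] if track else []

    Ft = F.T            # (K, S)
    Gt = (1.0 - F).T    # (K, S)
    for _ in range(max_iter):
        mix_alt = q @ Ft          # (B, S)
        mix_ref = q @ Gt
        with np.errstate(divide="ignore"):
            ll = (alt * np.log(mix_alt) + ref * np.log(mix_ref)).sum(axis=1)
        if track:
            for b in range(B):
                if not converged[b]:
                    paths[b].append(float(ll[b]))
        newly = (~converged) & (np.abs(ll - ll_prev) < tol)
        converged |= newly
        if converged.all():
            ll_prev = ll
            break
        # EM update: expected allele counts attributed to population k
        q_new = q * ((alt / np.maximum(mix_alt, 1e-300)) @ F
                     + (ref / np.maximum(mix_ref, 1e-300)) @ (1.0 - F)) \
            / np.maximum(2.0 * n_used, 1e-300)[:, None]
        q = np.where(converged[:, None], q, q_new)
        ll_prev = ll
    return q, ll_prev, converged, paths


def supervised_q(x: np.ndarray, f: np.ndarray,
                 track_loglik: bool = False) -> QVector:
    """Ancestry of one sample against fixed panel frequencies ``f``.

    EM starts at (1/3, 1/3, 1/3) and stops when the log-likelihood
    changes by < 1e-4 or after 2,000 iterations (non-convergence is
    flagged, not raised).  Missing sites are skipped.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != f.shape[0]:
        raise ValueError("sample and panel site sets differ")
    q, ll, conv, paths = _em_batch(x[None, :], f, track=track_loglik)
    if not conv[0]:
        log.warning("EM did not converge within %d iterations", EM_MAX_ITER)
    return QVector(
        q=q[0], n_sites=int((~np.isnan(x)).sum()),
        loglik=float(ll[0]), converged=bool(conv[0]),
        loglik_path=paths[0] if track_loglik else [],
    )


def bootstrap_se(x: np.ndarray, f: np.ndarray, n_boot: int = 10,
                 seed: int = 0) -> np.ndarray:
    """Bootstrap standard errors of q: sites resampled with replacement."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    S = x.shape[0]
    # resampling sites with replacement == multinomial site weights, so
    # all replicates share one batched EM against the fixed panel
    weights = rng.multinomial(S, np.full(S, 1.0 / S),
                              size=n_boot).astype(float)
    X = np.broadcast_to(x, (n_boot, S))
    q, _, _, _ = _em_batch(X, f, site_weights=weights)
    return q.std(axis=0, ddof=1)


def analyze_sample(x: np.ndarray, f: np.ndarray, n_boot: int = 10,
                   seed: int = 0) -> QVector:
    """Point estimate plus bootstrap SEs for one focal sample."""
    qv = supervised_q(x, f)
    qv.se = bootstrap_se(x, f, n_boot=n_boot, seed=seed)
    return qv


@dataclass
class PanelCounts:
    """Per-site alt/total allele counts of the labelled reference panels."""

    alt: np.ndarray   # (S, K) alt-allele counts per population
    tot: np.ndarray   # (S, K) called allele copies per population

    @classmethod
    def from_matrix(cls, M: GenotypeMatrix,
                    labels: dict[str, str]) -> "PanelCounts":
        alt = np.zeros((M.n_sites, len(POPS)))
        tot = np.zeros((M.n_sites, len(POPS)))
        idx = {s: j for j, s in enumerate(M.sample_ids)}
        for pop_i, pop in enumerate(POPS):
            ids = [s for s, p in labels.items() if p == pop]
            if len(ids) < 2:
                raise ValueError(f"reference population {pop} needs >= 2 samples")
            for s in ids:
                x = M.dosages[:, idx[s]]
                ok = ~np.isnan(x)
                alt[ok, pop_i] += x[ok]
                tot[ok, pop_i] += 2.0
        return cls(alt, tot)


def _joint_em_chunk(X: np.ndarray, alt: np.ndarray, tot: np.ndarray,
                    site_weights: np.ndarray | None = None,
                    tol_q: float = 1e-5, max_iter: int = EM_MAX_ITER):
    """Joint supervised EM for a chunk of focal samples.

    Panel genotypes enter the likelihood as binomial allele counts with
    population frequencies f re-estimated each M-step (panel members'
    memberships fixed pure; the focal sample contributes to f through
    its responsibilities).  This removes the attenuation that fixed
    noisy panel frequencies impose on q for low-divergence panels.
    Stops when every row's max |dq| < tol_q.  Returns (q, converged).
    """
    B, S = X.shape
    K = alt.shape[1]
    w = np.ones((B, S)) if site_weights is None else site_weights
    called_w = w * (~np.isnan(X))
    xw = np.nan_to_num(X, nan=0.0) * called_w
    rw = (2.0 - np.nan_to_num(X, nan=0.0)) * called_w
    n_used = called_w.sum(axis=1)
    altw = alt[None, :, :] * w[:, :, None]
    totw = tot[None, :, :] * w[:, :, None]

    def em_step(q, f, rows):
        mix = np.einsum("bsk,bk->bs", f, q)
        mixr = np.einsum("bsk,bk->bs", 1.0 - f, q)
        ra = (xw[rows][:, :, None] / np.maximum(mix, 1e-300)[:, :, None]) \
            * q[:, None, :] * f
        rr = (rw[rows][:, :, None] / np.maximum(mixr, 1e-300)[:, :, None]) \
            * q[:, None, :] * (1.0 - f)
        q_new = (ra.sum(axis=1) + rr.sum(axis=1)) \
            / np.maximum(2.0 * n_used[rows], 1e-300)[:, None]
        f_new = np.clip((altw[rows] + ra)
                        / np.maximum(totw[rows] + ra + rr, 1e-300),
                        1e-4, 1.0 - 1e-4)
        return q_new, f_new

    def project(q, f):
        q = np.clip(q, 1e-9, None)
        q = q / q.sum(axis=1, keepdims=True)
        return q, np.clip(f, 1e-4, 1.0 - 1e-4)

    q = np.full((B, K), 1.0 / K)
    f = np.broadcast_to(((alt + 0.5) / np.maximum(tot + 1.0, 1e-300)),
                        (B, S, K)).copy()
    active = np.arange(B)
    q_out = q.copy()
    conv = np.zeros(B, dtype=bool)
    # SQUAREM (SqS3) acceleration: each cycle costs 3 EM maps but
    # contracts the slow EM tail by an extrapolated step
    for _ in range(max_iter // 3 + 1):
        q1, f1 = em_step(q, f, active)
        q2, f2 = em_step(q1, f1, active)
        rq, rf = q1 - q, f1 - f
        vq, vf = (q2 - q1) - rq, (f2 - f1) - rf
        r2 = (rq**2).sum(axis=1) + (rf**2).sum(axis=(1, 2))
        v2 = (vq**2).sum(axis=1) + (vf**2).sum(axis=(1, 2))
        alpha = -np.sqrt(r2 / np.maximum(v2, 1e-300))
        alpha = np.clip(alpha, None, -1.0)[:, None]
        q_acc = q - 2.0 * alpha * rq + alpha**2 * vq
        f_acc = f - 2.0 * alpha[:, :, None] * rf + (alpha**2)[:, :, None] * vf
        q_acc, f_acc = project(q_acc, f_acc)
        q3, f3 = em_step(q_acc, f_acc, active)  # stabilisation step
        bad = ~np.isfinite(q3).all(axis=1)
        if bad.any():
            q3[bad], f3[bad] = q2[bad], f2[bad]
        dq = np.abs(q3 - q).max(axis=1)
        q, f = q3, f3
        done = dq < tol_q
        if done.any():
            q_out[active[done]] = q[done]
            conv[active[done]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            q, f = q[keep], f[keep]
    if active.size:
        q_out[active] = q
    return q_out, conv


def joint_analyze_samples(M: GenotypeMatrix, labels: dict[str, str],
                          sample_ids: list[str], n_boot: int = 10,
                          seed: int = 0, chunk: int = 128,
                          threshold: float = 0.98
                          ) -> tuple[pd.DataFrame, dict[str, QVector]]:
    """Joint supervised ancestry + bootstrap SEs for many focal samples.

    Each focal sample is analysed independently (one at a time against
    the panels — estimates never depend on other focal samples); the
    bootstrap resamples sites via multinomial weights.  Work is batched
    in chunks for speed.  Returns the tidy table and QVectors.
    """
    panel = PanelCounts.from_matrix(M, labels)
    idx = {s: j for j, s in enumerate(M.sample_ids)}
    S = M.n_sites
    rng = np.random.default_rng(seed)
    rows_X, rows_W = [], []
    for sid in sample_ids:
        x = M.dosages[:, idx[sid]]
        rows_X.append(x)
        rows_W.append(np.ones(S))
        for _ in range(n_boot):
            rows_X.append(x)
            rows_W.append(rng.multinomial(S, np.full(S, 1.0 / S)).astype(float))
    X = np.vstack(rows_X)
    W = np.vstack(rows_W)
    Q = np.empty((X.shape[0], len(POPS)))
    CONV = np.empty(X.shape[0], dtype=bool)
    for start in range(0, X.shape[0], chunk):
        sl = slice(start, min(start + chunk, X.shape[0]))
        Q[sl], CONV[sl] = _joint_em_chunk(X[sl], panel.alt, panel.tot,
                                          site_weights=W[sl])
    out_rows, qvs = [], {}
    per = n_boot + 1
    for k, sid in enumerate(sample_ids):
        q = Q[k * per]
        se = Q[k * per + 1: (k + 1) * per].std(axis=0, ddof=1)
        qv = QVector(q=q, se=se,
                     n_sites=int((~np.isnan(M.dosages[:, idx[sid]])).sum()),
                     converged=bool(CONV[k * per]))
        call = purity_call(qv, threshold=threshold)
        qvs[sid] = qv
        out_rows.append({
            "sample_id": sid,
            **{f"q_{p}": qv.q[i] for i, p in enumerate(POPS)},
            **{f"se_{p}": qv.se[i] for i, p in enumerate(POPS)},
            "n_sites": qv.n_sites, "call": call.label, "pure": call.pure,
        })
    return pd.DataFrame(out_rows), qvs


def purity_call(qv: QVector, threshold: float = 0.98,
                minor_component_floor: float = 0.10) -> SpeciesCall:
    """Pure/hybrid species call from a QVector.

    A sample is genetically pure for population k when ``q_k + se_k``
    reaches the purity threshold (default 98%).  Otherwise the label is
    the hybrid composite of every component with ``q`` above the minor-
    component floor, in ABDU, WMA, GFM order (e.g. ``ABDUxWMA``).
    """
    se = qv.se if qv.se is not None else np.zeros_like(qv.q)
    reach = qv.q + se
    if reach.max() >= threshold:
        return SpeciesCall(label=POPS[int(np.argmax(reach))], pure=True)
    parts = [p for p, qk in zip(POPS, qv.q) if qk > minor_component_floor]
    if not parts:
        parts = [POPS[int(np.argmax(qv.q))]]
    return SpeciesCall(label="x".join(parts), pure=False)


def infer_paternal_q(mother: QVector,
                     offspring: list[QVector]) -> QVector:
    """Paternal ancestry by subtraction over a paternal sib-group.

    Each offspring inherits half of each parent's ancestry, so
    ``q_father = 2 q_offspring - q_mother`` (clipped at 0 and
    renormalised).  The sib-group estimate is the component-wise mean;
    its spread across the sib-group is propagated as the SE.
    """
    if not offspring:
        raise ValueError("empty sib-group")
    ests = []
    for off in offspring:
        est = np.clip(2.0 * off.q - mother.q, 0.0, None)
        tot = est.sum()
        ests.append(est / tot if tot > 0 else np.full_like(est, 1.0 / len(est)))
    ests = np.vstack(ests)
    return QVector(q=ests.mean(axis=0), se=ests.std(axis=0, ddof=0),
                   n_sites=min(o.n_sites for o in offspring))


def ancestry_table(M: GenotypeMatrix, f: np.ndarray, sample_ids: list[str],
                   threshold: float = 0.98, n_boot: int = 10,
                   seed: int = 0) -> tuple[pd.DataFrame, dict[str, QVector]]:
    """Run each focal sample independently against the fixed panels.

    Returns a tidy table (sample_id, q_*, se_*, n_sites, call, pure) and
    the underlying QVectors.  Estimates for one sample do not depend on
    which other focal samples are present.
    """
    idx = {s: j for j, s in enumerate(M.sample_ids)}
    rows, qvs = [], {}
    for k, sid in enumerate(sample_ids):
        x = M.dosages[:, idx[sid]]
        qv = analyze_sample(x, f, n_boot=n_boot,
                            seed=(seed * 100003 + k) % (2**31))
        call = purity_call(qv, threshold=threshold)
        qvs[sid] = qv
        rows.append({
            "sample_id": sid,
            **{f"q_{p}": qv.q[i] for i, p in enumerate(POPS)},
            **{f"se_{p}": qv.se[i] for i, p in enumerate(POPS)},
            "n_sites": qv.n_sites, "call": call.label, "pure": call.pure,
        })
    return pd.DataFrame(rows), qvs
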