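"""Population-level geometry of the condition tensor.

* instantaneous marginal variance per task variable (side, outcome,
  difficulty):  Var_m(t) = (1/N) sum_i sum_m (r_i(t,m) - rbar_i(t))^2,
  where r_i(t,m) averages over the non-marginalized condition axes;
* cosine self-similarity of population vectors across timepoints,
  optionally after removing condition-independent (temporal) dynamics;
* PCA of the unit-by-unit covariance over all condition-time samples, with
  shuffle-based eigenvalue significance (per-unit time shuffling destroys
  cross-unit temporal correlation);
* demixed PCA: a balanced ANOVA-style additive decomposition of the
  centered tensor into condition-independent (time), per-factor, and
  residual parts, followed by PCA of each part's covariance and projection
  of the full centered data onto the demixed axes;
* kinematically matched trajectory selection (correlation with per-side Go
  model trajectories) and the context (Return vs Go) tensor built from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics_events import KinematicsTable
from .peth import PETHTensor, rate_estimate
from .session_io import AnalysisConfig, SessionBundle

#: condition-axis position of each marginalization in the S x D x C tensor
TENSOR_AXES = {"side": 1, "difficulty": 2, "outcome": 3}


# ---------------------------------------------------------------------------
# variance and similarity
# ---------------------------------------------------------------------------


def instantaneous_variance(
    tensor: PETHTensor, marginalization: str
) -> np.ndarray:
    """Instantaneous variance trace for one marginalization (units^2).

    The tensor is first averaged over the non-marginalized condition axes;
    the trace sums squared deviations of the per-level means from the
    condition-independent mean, averaged over units.
    """
    if marginalization not in TENSOR_AXES:
        raise ValueError(f"unknown marginalization {marginalization!r}")
    axis = TENSOR_AXES[marginalization]
    X = tensor.data  # (N, S, D, C, T)
    other = tuple(a for a in (1, 2, 3) if a != axis)
    per_level = X.mean(axis=other)  # (N, L, T)
    grand = X.mean(axis=(1, 2, 3))  # (N, T)
    dev = per_level - grand[:, None, :]
    return (dev**2).sum(axis=1).mean(axis=0)


def variance_traces(tensor: PETHTensor) -> dict[str, np.ndarray]:
    """All three marginal variance traces of the S x D x C tensor."""
    return {m: instantaneous_variance(tensor, m) for m in TENSOR_AXES}


def demean_tensor(tensor: PETHTensor) -> PETHTensor:
    """Remove condition-independent (temporal) dynamics: per unit and time
    bin, subtract the across-condition mean."""
    X = tensor.data
    mean = X.mean(axis=(1, 2, 3), keepdims=True)
    return tensor.copy_with(X - mean)


def cosine_similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of column vectors (features x T).

    Zero-norm columns yield NaN (masked) rows/columns.
    """
    norms = np.linalg.norm(vectors, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = vectors / norms[None, :]
        cs = unit.T @ unit
    cs[norms == 0, :] = np.nan
    cs[:, norms == 0] = np.nan
    return np.clip(cs, -1.0, 1.0, out=cs)


def cosine_self_similarity(tensor: PETHTensor, demean: bool = True) -> np.ndarray:
    """T x T cosine similarity of population vectors across timepoints.

    The population vector at time t concatenates all units' responses over
    the condition cells.  With ``demean`` the condition-independent temporal
    dynamics are removed first.
    """
    t = demean_tensor(tensor) if demean else tensor
    X = t.data
    feats = X.reshape(-1, X.shape[-1])  # (N * S * D * C, T)
    return cosine_similarity_matrix(feats)


# ---------------------------------------------------------------------------
# PCA with shuffle significance
# ---------------------------------------------------------------------------


def _condition_samples(X: np.ndarray) -> np.ndarray:
    """Flatten condition and time axes into samples: (N, n_samples)."""
    return X.reshape(X.shape[0], -1)


def _covariance_eig(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition (descending) of the unit x unit covariance."""
    centered = samples - samples.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / samples.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


class ConditionPCA:
    """PCA of the pseudo-population covariance over condition-time samples.

    Follows the scikit-learn estimator idiom: ``fit`` on a condition tensor
    array (units first, time last), then ``transform`` projects data onto
    the eigenvectors by dot product.

    Attributes
    ----------
    eigenvalues_ : (N,) descending
    components_ : (N, N) eigenvectors in rows, unit norm
    explained_variance_ratio_ : fractions summing to 1
    significant_ : boolean flags (only with n_shuffles > 0)
    null_eigenvalues_ : (n_shuffles, N) shuffled eigenvalue distributions
    """

    def __init__(
        self,
        n_shuffles: int = 0,
        alpha: float = 0.01,
        shuffle: str = "rotate",
        random_state: int | None = None,
    ):
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.shuffle = shuffle
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_shuffles": self.n_shuffles,
            "alpha": self.alpha,
            "shuffle": self.shuffle,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "ConditionPCA":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit(self, X: np.ndarray) -> "ConditionPCA":
        X = np.asarray(X, float)
        if not np.all(np.isfinite(X)):
            raise ValueError("tensor contains non-finite values")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 units")
        samples = _condition_samples(X)
        vals, vecs = _covariance_eig(samples)
        self.eigenvalues_ = np.maximum(vals, 0.0)
        self.components_ = vecs.T
        total = self.eigenvalues_.sum()
        self.explained_variance_ratio_ = (
            self.eigenvalues_ / total if total > 0 else self.eigenvalues_
        )
        if self.n_shuffles:
            null = shuffled_eigenvalue_null(
                X,
                lambda Xs: _covariance_eig(_condition_samples(Xs))[0],
                n_shuffles=self.n_shuffles,
                mode=self.shuffle,
                random_state=self.random_state,
            )
            self.null_eigenvalues_ = null
            self.significant_ = eigenvalue_significance(
                self.eigenvalues_, null, self.alpha
            )
        return self

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Project data onto the leading eigenvectors (dot product);
        output shape (n_components, *X.shape[1:])."""
        k = n_components or len(self.eigenvalues_)
        Xc = X - _condition_samples(X).mean(axis=1).reshape(
            (-1,) + (1,) * (X.ndim - 1)
        )
        return np.tensordot(self.components_[:k], Xc, axes=(1, 0))


def shuffled_eigenvalue_null(
    X: np.ndarray,
    eig_fn,
    n_shuffles: int = 1000,
    mode: str = "rotate",
    random_state: int | None = None,
) -> np.ndarray:
    """Null eigenvalue distributions from per-unit time-shuffled tensors.

    ``rotate`` circularly rolls each unit's time axis by an independent
    uniform offset (preserving its autocorrelation); ``permute`` applies an
    independent random permutation of time bins per unit.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for quantile stability")
    rng = np.random.default_rng(random_state)
    n_t = X.shape[-1]
    out = []
    for _ in range(n_shuffles):
        Xs = np.empty_like(X)
        for i in range(X.shape[0]):
            if mode == "rotate":
                Xs[i] = np.roll(X[i], int(rng.integers(n_t)), axis=-1)
            elif mode == "permute":
                Xs[i] = X[i][..., rng.permutation(n_t)]
            else:
                raise ValueError(f"unknown shuffle mode {mode!r}")
        out.append(eig_fn(Xs))
    return np.asarray(out)


def eigenvalue_significance(
    eigenvalues: np.ndarray, null: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Per-rank comparison to the shuffled null with a contiguous-from-first
    rule: component k is significant if its eigenvalue exceeds the
    (1 - alpha) null quantile of rank-k eigenvalues and all earlier
    components are significant."""
    k = min(len(eigenvalues), null.shape[1])
    thresh = np.quantile(null[:, :k], 1.0 - alpha, axis=0)
    flags = np.zeros(len(eigenvalues), bool)
    for i in range(k):
        if eigenvalues[i] > thresh[i]:
            flags[i] = True
        else:
            break
    return flags


# ---------------------------------------------------------------------------
# demixed PCA
# ---------------------------------------------------------------------------


def dpca_parts(
    X: np.ndarray, factor_axes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Additive marginalization of a centered condition tensor.

    ``X`` has units on axis 0 and time on the last axis; ``factor_axes``
    maps factor names to their condition axes.  Returns parts keyed by
    ``time``, each factor name, and ``residual``; the parts sum exactly to
    the tensor minus each unit's grand mean.  In this balanced design the
    parts are mutually orthogonal, so their variances add to the total.
    """
    cond_axes = tuple(factor_axes.values())
    grand = X.mean(axis=cond_axes + (X.ndim - 1,), keepdims=True)
    Xc = X - grand
    time_part = Xc.mean(axis=cond_axes, keepdims=True)
    parts: dict[str, np.ndarray] = {"time": np.broadcast_to(time_part, X.shape).copy()}
    resid = Xc - time_part
    for name, axis in factor_axes.items():
        other = tuple(a for a in cond_axes if a != axis)
        fpart = Xc.mean(axis=other, keepdims=True) - time_part
        parts[name] = np.broadcast_to(fpart, X.shape).copy()
        resid = resid - fpart
    parts["residual"] = resid
    return parts


@dataclass
class DemixedResult:
    """Demixed components per marginalization, sorted by explained variance."""

    eigenvalues: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]  # (n_units, n_comp), columns unit norm
    etv: dict[str, np.ndarray]  # explained-total-variance fractions
    components: dict[str, np.ndarray]  # projections of the centered data
    total_variance: float
    significant: dict[str, np.ndarray] = field(default_factory=dict)

    def ranking(self) -> list[tuple[str, int, float]]:
        """All components across marginalizations sorted by ETV descending."""
        rows = [
            (name, k, float(self.etv[name][k]))
            for name in self.etv
            for k in range(len(self.etv[name]))
        ]
        return sorted(rows, key=lambda r: r[2], reverse=True)


class DemixedPCA:
    """Demixed PCA as described above: marginalize, eigendecompose each
    part's unit covariance, project the full centered data.

    Parameters
    ----------
    marginalizations : factor names to demix (besides ``time`` and the
        pooled ``residual``); must be keys of the ``factor_axes`` passed to
        ``fit``.
    n_components : components kept per marginalization.
    n_shuffles : if > 0, per-marginalization eigenvalue significance against
        per-unit time-shuffled tensors at level ``alpha``.
    """

    def __init__(
        self,
        marginalizations: tuple[str, ...] | None = None,
        n_components: int = 10,
        n_shuffles: int = 0,
        alpha: float = 0.01,
        shuffle: str = "rotate",
        random_state: int | None = None,
    ):
        self.marginalizations = marginalizations
        self.n_components = n_components
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.shuffle = shuffle
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "marginalizations": self.marginalizations,
            "n_components": self.n_components,
            "n_shuffles": self.n_shuffles,
            "alpha": self.alpha,
            "shuffle": self.shuffle,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "DemixedPCA":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit(
        self, X: np.ndarray, factor_axes: dict[str, int] | None = None
    ) -> "DemixedPCA":
        X = np.asarray(X, float)
        factor_axes = factor_axes or TENSOR_AXES
        wanted = self.marginalizations or tuple(factor_axes)
        unknown = set(wanted) - set(factor_axes)
        if unknown:
            raise ValueError(f"unknown marginalization(s): {sorted(unknown)}")
        parts = dpca_parts(X, {k: factor_axes[k] for k in factor_axes})
        keep = ("time",) + tuple(wanted)

        Xc = X - X.mean(axis=tuple(range(1, X.ndim)), keepdims=True)
        total_var = float((_condition_samples(Xc) ** 2).mean(axis=1).sum())

        eigs, weights, etv, comps = {}, {}, {}, {}
        for name in keep:
            vals, vecs = _covariance_eig(_condition_samples(parts[name]))
            k = min(self.n_components, len(vals))
            eigs[name] = np.maximum(vals[:k], 0.0)
            weights[name] = vecs[:, :k]
            etv[name] = eigs[name] / total_var if total_var > 0 else eigs[name]
            comps[name] = np.tensordot(vecs[:, :k].T, Xc, axes=(1, 0))

        significant = {}
        if self.n_shuffles:
            axes_used = {k: factor_axes[k] for k in factor_axes}

            for name in keep:

                def eig_fn(Xs, _name=name):
                    p = dpca_parts(Xs, axes_used)[_name]
                    return _covariance_eig(_condition_samples(p))[0]

                null = shuffled_eigenvalue_null(
                    X,
                    eig_fn,
                    n_shuffles=self.n_shuffles,
                    mode=self.shuffle,
                    random_state=self.random_state,
                )
                significant[name] = eigenvalue_significance(
                    eigs[name], null, self.alpha
                )

        self.parts_ = parts
        self.result_ = DemixedResult(
            eigenvalues=eigs,
            weights=weights,
            etv=etv,
            components=comps,
            total_variance=total_var,
            significant=significant,
        )
        return self

    def transform(self, X: np.ndarray, marginalization: str = "time") -> np.ndarray:
        Xc = np.asarray(X, float)
        Xc = Xc - Xc.mean(axis=tuple(range(1, Xc.ndim)), keepdims=True)
        return np.tensordot(
            self.result_.weights[marginalization].T, Xc, axes=(1, 0)
        )


def dpca(
    tensor: PETHTensor,
    marginalizations: tuple[str, ...] = ("side", "difficulty", "outcome"),
    n_shuffles: int = 0,
    alpha: float = 0.01,
    random_state: int | None = None,
) -> DemixedResult:
    """Demixed PCA of the S x D x C condition tensor."""
    est = DemixedPCA(
        marginalizations=marginalizations,
        n_shuffles=n_shuffles,
        alpha=alpha,
        random_state=random_state,
    )
    est.fit(tensor.data, TENSOR_AXES)
    return est.result_


# ---------------------------------------------------------------------------
# trajectory matching and the context tensor
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryMatchSet:
    """Kinematically matched trial selection for the context analysis."""

    models: dict[str, np.ndarray]  # side -> (2, n_points) speed; angular velocity
    selected: dict[str, list[int]]  # condition label -> trial indices
    correlations: dict[int, float]  # trial index -> r with its side model
    r_min: float


def _trial_profile(
    kin: KinematicsTable, t0: float, t1: float, n_points: int
) -> np.ndarray:
    ts = np.linspace(t0, t1, n_points)
    return np.vstack([kin.interp("body_speed", ts), kin.interp("angular_velocity", ts)])


def _profile_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Correlation of two (2, n) profiles after per-variable standardization."""
    rows = []
    for va, vb in zip(a, b):
        sa, sb = va.std(), vb.std()
        rows.append(((va - va.mean()) / (sa if sa else 1.0),
                     (vb - vb.mean()) / (sb if sb else 1.0)))
    x = np.concatenate([r[0] for r in rows])
    y = np.concatenate([r[1] for r in rows])
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def match_trajectories(
    bundle: SessionBundle,
    events: dict[int, dict[str, float]],
    kin: KinematicsTable,
    r_min: float = 0.75,
    n_points: int = 50,
) -> TrajectoryMatchSet:
    """Select Return and Go trials whose (speed, angular velocity) profile
    correlates at least ``r_min`` with the side-matched mean Go model.

    The Go displacement window is turn end to port entry; the Return window
    is return start to wait arrival (its side is the port the animal returns
    from, i.e. the previous trial's choice).
    """
    go_profiles: dict[str, list[tuple[int, np.ndarray]]] = {"left": [], "right": []}
    ret_profiles: dict[str, list[tuple[int, np.ndarray]]] = {"left": [], "right": []}
    prev_choice: str | None = None
    for tr in bundle.trials:
        ev = events.get(tr.index)
        if ev:
            if "turn_end" in ev and "port_entry" in ev:
                go_profiles[tr.choice].append(
                    (tr.index, _trial_profile(kin, ev["turn_end"], ev["port_entry"], n_points))
                )
            if prev_choice and "return_start" in ev and "wait_arrival" in ev:
                ret_profiles[prev_choice].append(
                    (tr.index, _trial_profile(kin, ev["return_start"], ev["wait_arrival"], n_points))
                )
        prev_choice = tr.choice

    models = {}
    for side in ("left", "right"):
        if len(go_profiles[side]) < 3:
            raise ValueError(f"fewer than 3 Go trials on side {side!r}")
        models[side] = np.mean([p for _, p in go_profiles[side]], axis=0)

    selected: dict[str, list[int]] = {
        "Return-L": [], "Return-R": [], "Go-L": [], "Go-R": []
    }
    correlations: dict[int, float] = {}
    for side, label in (("left", "Go-L"), ("right", "Go-R")):
        for idx, prof in go_profiles[side]:
            r = _profile_corr(prof, models[side])
            correlations[idx] = r
            if r >= r_min:
                selected[label].append(idx)
    for side, label in (("left", "Return-L"), ("right", "Return-R")):
        for idx, prof in ret_profiles[side]:
            r = _profile_corr(prof, models[side])
            correlations.setdefault(idx, r)
            if r >= r_min:
                selected[label].append(idx)
    return TrajectoryMatchSet(
        models=models, selected=selected, correlations=correlations, r_min=r_min
    )


CONTEXT_AXES = {"context": 1, "side": 2}


def build_context_tensor(
    bundle: SessionBundle,
    events: dict[int, dict[str, float]],
    match: TrajectoryMatchSet,
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average firing of matched trials into a units x context x side x T
    tensor (context: Return vs Go; each trajectory linearly rescaled to the
    mean selected-Go duration).  Returns (tensor, canonical time grid)."""
    cfg = cfg or AnalysisConfig()
    windows: dict[str, list[tuple[float, float]]] = {k: [] for k in match.selected}
    for label, indices in match.selected.items():
        for idx in indices:
            ev = events[idx]
            if label.startswith("Go"):
                windows[label].append((ev["turn_end"], ev["port_entry"]))
            else:
                windows[label].append((ev["return_start"], ev["wait_arrival"]))
    all_durs = [b - a for spans in windows.values() for a, b in spans]
    if not all_durs:
        raise ValueError("no matched trajectories")
    mean_dur = float(np.mean(all_durs))
    grid = np.arange(0.0, mean_dur + cfg.peth_step / 2, cfg.peth_step)
    n_t = len(grid)

    order = {
        ("Return", "left"): "Return-L",
        ("Return", "right"): "Return-R",
        ("Go", "left"): "Go-L",
        ("Go", "right"): "Go-R",
    }
    tensor = np.zeros((bundle.n_units, 2, 2, n_t))
    pad = 6 * cfg.smoothing_sigma
    for ui, st in enumerate(bundle.spikes):
        for (ci, ctx), (si, side) in (
            ((ci, ctx), (si, side))
            for ci, ctx in enumerate(("Return", "Go"))
            for si, side in enumerate(("left", "right"))
        ):
            spans = windows[order[(ctx, side)]]
            if not spans:
                continue
            acc = np.zeros(n_t)
            for a, b in spans:
                tgrid = np.arange(a - pad, b + pad, cfg.peth_step)
                sel = st.times[(st.times >= a - 2 * pad) & (st.times <= b + 2 * pad)]
                rate = rate_estimate(sel, tgrid, cfg.smoothing_sigma)
                warped_t = a + (grid / mean_dur) * (b - a)
                acc += np.interp(warped_t, tgrid, rate)
            tensor[ui, ci, si] = acc / len(spans)
    return tensor, grid
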