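"""Per-subject calibration: template banking, AUROC screening, stepwise selection.

The calibration wrapper answers four questions for one subject from labeled
training epochs alone: which electrodes carry a detectable P300, how many
stimulations K' must be averaged, which averaged-trial template best
represents the subject's P300 per electrode, and which shape features are
worth keeping.

For each candidate stimulation count k (starting at the acquisition maximum
K and decreasing), and for each electrode, O candidate templates are built
by coherently averaging A randomly chosen P300 trials and chain-coding the
average. Each template is scored by U cross-validation folds: every fold
averages k fresh P300 trials (disjoint from the template's trials and from
other folds) and k non-P300 trials, extracts the shape-feature vector of
each against the template, and the AUROC of the template-to-average chain
distances separates the two classes. Averaging the O AUROCs per electrode
gives the screening score phi; electrodes with phi >= 0.8 are accepted, and
k keeps decreasing while any electrode is accepted. Feature reduction is a
forward-entry (p < p_enter) / backward-removal (p > p_remove) stepwise
least-squares regression of +1/-1 class labels on the 2U x (2S+2) feature
block of each (electrode, template).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .epochs import NONP300, P300, EpochSet, random_subset
from .preprocess import Curve, coherent_average
from .shcc import Chain, chain_distance, encode_chain, format_chain, normalize_curve, parse_chains, resample_curve, tortuosity
from .shape_features import ShapeFeatureVector, area_difference_features, assemble_vector, feature_names

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationParams",
    "TemplateBank",
    "ScoreMatrix",
    "CalibrationProfile",
    "StepwiseResult",
    "build_template",
    "feature_pair",
    "auroc",
    "stepwise_select",
    "average_auroc",
    "select_electrodes",
    "calibrate",
    "n_folds",
]


@dataclass
class CalibrationParams:
    """Tunable knobs of the calibration wrapper.

    Defaults follow the reference acquisition regime: S = 16 segments,
    A = 180 trials per template, K = 15 stimulations, AUROC acceptance at
    0.8 with a 0.6 fallback, stepwise p-to-enter 0.1 / p-to-remove 0.15.
    """

    segments: int = 16
    trials_per_template: int = 180
    max_stimulations: int = 15
    templates_per_electrode: int = 10
    auroc_accept: float = 0.8
    auroc_fallback: float = 0.6
    p_enter: float = 0.1
    p_remove: float = 0.15
    max_folds: int = 20
    codec_mode: str = "slope"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.auroc_fallback < self.auroc_accept <= 1:
            raise ValueError("need 0 < auroc_fallback < auroc_accept <= 1")
        if not 0 < self.p_enter < self.p_remove < 1:
            raise ValueError("need 0 < p_enter < p_remove < 1")
        for name in ("segments", "trials_per_template", "max_stimulations",
                     "templates_per_electrode", "max_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def validate_against(self, train: EpochSet) -> None:
        P = train.count(P300)
        if self.trials_per_template + self.max_stimulations > P:
            raise ValueError(
                f"A + K = {self.trials_per_template + self.max_stimulations} "
                f"exceeds the {P} available P300 trials"
            )


def n_folds(n_p300: int, trials_per_template: int, k: int, cap: int | None = None) -> int:
    """Cross-validation folds U = floor((P - A) / k), optionally capped."""
    u = (n_p300 - trials_per_template) // k
    return min(u, cap) if cap is not None else u


@dataclass
class TemplateBank:
    """Per-electrode candidate templates: averaged curves and their chains."""

    electrode: str
    curves: list[Curve]
    chains: list[Chain]
    used_indices: list[np.ndarray]

    def __post_init__(self) -> None:
        if not all(len(ch) == len(self.chains[0]) for ch in self.chains):
            raise ValueError("all template chains must share one length S")


@dataclass
class ScoreMatrix:
    """AUROC matrix Z (templates x electrodes) and per-electrode means phi."""

    Z: np.ndarray
    electrode_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != len(self.electrode_names):
            raise ValueError("Z must be O x C with one column per electrode")
        if np.any((self.Z < 0) | (self.Z > 1)):
            raise ValueError("AUROC entries must lie in [0, 1]")

    @property
    def phi(self) -> np.ndarray:
        return average_auroc(self.Z)


@dataclass
class StepwiseResult:
    """Outcome of one stepwise regression: mask, weights, and retained columns."""

    mask: np.ndarray          # boolean over the V input columns
    weights: np.ndarray       # coefficients of the retained columns, model order
    intercept: float
    features: np.ndarray      # the retained column values (n x I)
    pvalues: np.ndarray       # final-model p-value per retained column

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


# ---------------------------------------------------------------------------
# Template construction and feature extraction


def build_template(
    p300_trials: EpochSet,
    trials_per_template: int,
    segments: int,
    seed: int | np.random.SeedSequence,
    mode: str = "slope",
) -> tuple[Curve, Chain, np.ndarray]:
    """Average A random P300 trials of one electrode and chain-code the result.

    Returns the averaged template curve, its chain, and the trial indices
    consumed (to be excluded from cross-validation folds).
    """
    subset, idx = random_subset(p300_trials, P300, trials_per_template, seed)
    curve = coherent_average(subset)
    return curve, encode_chain(curve, segments, mode), idx


def feature_pair(
    template_curve: Curve,
    template_chain: Chain,
    trials: EpochSet,
    label: str,
    k: int,
    segments: int,
    seed: int | np.random.SeedSequence,
    exclude: Sequence[int] | None = None,
    mode: str = "slope",
) -> tuple[ShapeFeatureVector, np.ndarray]:
    """Average k random trials of one class and featurize against the template.

    The candidate average is chain-coded; the vector stacks the signed
    template-minus-candidate trapezoid-area differences, their absolute sum,
    the template-to-candidate chain distance, the candidate's tortuosity,
    and the candidate's chain symbols.
    """
    subset, idx = random_subset(trials, label, k, seed, exclude=exclude)
    candidate_curve = coherent_average(subset)
    cand_chain = encode_chain(candidate_curve, segments, mode)
    t_norm = normalize_curve(resample_curve(template_curve, segments))
    c_norm = normalize_curve(resample_curve(candidate_curve, segments))
    diffs, dsum = area_difference_features(t_norm, c_norm)
    d = chain_distance(template_chain, cand_chain)
    vec = assemble_vector(diffs, dsum, d, tortuosity(cand_chain), cand_chain)
    return vec, idx


# ---------------------------------------------------------------------------
# AUROC from template-to-average distances


def auroc(distances_p300: Sequence[float], distances_nonp300: Sequence[float]) -> float:
    """Area under the ROC for separating the classes by chain distance.

    Oriented so that *smaller* P300-to-template distances score toward 1;
    equivalent to the normalized Mann-Whitney statistic
    (#{dP < dN} + 0.5 #{dP = dN}) / (|dP| |dN|), computed from pooled ranks.
    """
    dp = np.asarray(distances_p300, dtype=float)
    dn = np.asarray(distances_nonp300, dtype=float)
    if dp.size == 0 or dn.size == 0:
        raise ValueError("both distance samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([dp, dn]))
    # rank-sum of the P class counts #{dP > dN} + 0.5 ties; invert for "smaller wins"
    u_greater = ranks[: dp.size].sum() - dp.size * (dp.size + 1) / 2.0
    return float(1.0 - u_greater / (dp.size * dn.size))


def average_auroc(Z: np.ndarray) -> np.ndarray:
    """Per-electrode mean AUROC phi: column-wise mean over the O templates."""
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        raise ValueError("empty score matrix")
    return Z.mean(axis=0)


def select_electrodes(
    phi: np.ndarray, accept: float = 0.8, fallback: float = 0.6
) -> tuple[np.ndarray, str]:
    """Threshold the per-electrode phi scores.

    Returns the selected electrode indices and a status: ``"accept"`` when
    any electrode reaches the accept threshold (keep iterating),
    ``"fallback"`` when only the weaker ``phi > fallback`` criterion is met
    (stop), or ``"unsuitable"`` when no electrode clears either bar — the
    subject's P300 cannot be found with these data.
    """
    phi = np.asarray(phi, dtype=float)
    selected = np.flatnonzero(phi >= accept)
    if selected.size:
        return selected, "accept"
    selected = np.flatnonzero(phi > fallback)
    if selected.size:
        return selected, "fallback"
    return selected, "unsuitable"


# ---------------------------------------------------------------------------
# Stepwise regression (SWLDA feature reduction)


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefs, p-values, rss).

    p-values are two-sided t-tests on each non-intercept coefficient with
    n - p residual degrees of freedom.
    """
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    p = design.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    df = n - p
    if df <= 0 or rank < p:
        return beta, np.full(X.shape[1], np.nan), rss
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 1e-300, None))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return beta, pvals[1:], rss


def _is_redundant(x: np.ndarray, design: np.ndarray, tol: float = 1e-8) -> bool:
    """True when *x* is (numerically) in the span of the current design."""
    norm = np.linalg.norm(x)
    if norm < tol:
        return True
    coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    return np.linalg.norm(resid) < tol * max(norm, 1.0)


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.1,
    p_remove: float = 0.15,
    max_steps: int = 1000,
) -> StepwiseResult:
    """Forward-entry / backward-removal stepwise least-squares regression.

    At each step the candidate column with the smallest two-sided p-value is
    entered if that p-value is below *p_enter*; then columns whose p-value in
    the refitted model exceeds *p_remove* are removed (worst first). The
    procedure is deterministic given (X, y); degenerate columns (constant,
    or collinear with the current model) are skipped with a debug note.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per element of y")
    n, V = X.shape
    active: list[int] = []
    for _ in range(max_steps):
        changed = False
        # forward step
        design = np.column_stack([np.ones(n), X[:, active]]) if active else np.ones((n, 1))
        best_j, best_p = -1, np.inf
        for j in range(V):
            if j in active:
                continue
            if n - (len(active) + 2) <= 0:
                break  # no residual degrees of freedom left
            if _is_redundant(X[:, j], design):
                logger.debug("stepwise: column %d degenerate/collinear; skipped", j)
                continue
            _, pv, _ = _ols_pvalues(X[:, active + [j]], y)
            pj = pv[-1]
            if np.isfinite(pj) and pj < best_p:
                best_p, best_j = pj, j
        if best_j >= 0 and best_p < p_enter:
            active.append(best_j)
            changed = True
        # backward steps
        while active:
            _, pv, _ = _ols_pvalues(X[:, active], y)
            worst = int(np.nanargmax(pv))
            if np.isnan(pv[worst]) or pv[worst] > p_remove:
                active.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    active_sorted = sorted(active)
    mask = np.zeros(V, dtype=bool)
    mask[active_sorted] = True
    if active_sorted:
        beta, pv, _ = _ols_pvalues(X[:, active_sorted], y)
        return StepwiseResult(mask, beta[1:], float(beta[0]), X[:, active_sorted], pv)
    return StepwiseResult(mask, np.empty(0), float(y.mean()), X[:, []], np.empty(0))


# ---------------------------------------------------------------------------
# Calibration profile and the principal wrapper


@dataclass
class ElectrodeProfile:
    """Selected template and reduced feature model for one electrode."""

    electrode: str
    template_index: int
    template_curve: Curve
    template_chain: Chain
    feature_mask: np.ndarray
    weights: np.ndarray
    intercept: float
    auroc: float


@dataclass
class CalibrationProfile:
    """Everything the wrapper returns: c', K', per-electrode templates and models."""

    status: str  # "ok" | "fallback" | "unsuitable"
    electrodes: tuple[str, ...]
    optimum_stimulations: int
    segments: int
    codec_mode: str
    per_electrode: dict[str, ElectrodeProfile]
    history: list[dict] = field(default_factory=list)  # per-k: k, U, phi, Z
    feature_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def phi_trace(self) -> list[tuple[int, np.ndarray]]:
        """(k, phi-per-electrode) pairs, in the order iterated."""
        return [(h["k"], np.asarray(h["phi"])) for h in self.history]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "electrodes": list(self.electrodes),
            "optimum_stimulations": self.optimum_stimulations,
            "segments": self.segments,
            "codec_mode": self.codec_mode,
            "per_electrode": {
                name: {
                    "template_index": ep.template_index,
                    "template_curve_y": ep.template_curve.y.tolist(),
                    "template_chain": format_chain(ep.template_chain),
                    "feature_mask": "".join(
                        "1" if b else "0" for b in ep.feature_mask
                    ),
                    "weights": ep.weights.tolist(),
                    "intercept": ep.intercept,
                    "auroc": ep.auroc,
                }
                for name, ep in self.per_electrode.items()
            },
            "history": [
                {
                    "k": h["k"],
                    "U": h["U"],
                    "status": h["status"],
                    "phi": np.asarray(h["phi"]).tolist(),
                    "Z": np.asarray(h["Z"]).tolist(),
                    "electrode_names": list(h["electrode_names"]),
                }
                for h in self.history
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
        )

    def save_text(self, path: str | Path) -> None:
        """Human-readable profile: electrodes, K', chains, masks, weights."""
        lines = [
            "# calibration profile",
            f"status: {self.status}",
            f"optimum_stimulations: {self.optimum_stimulations}",
            f"segments: {self.segments}",
            f"electrodes: {' '.join(self.electrodes) if self.electrodes else '(none)'}",
        ]
        names = feature_names(self.segments)
        for name, ep in self.per_electrode.items():
            sel = [names[i] for i in np.flatnonzero(ep.feature_mask)]
            lines += [
                "",
                f"[electrode {name}]",
                f"auroc: {ep.auroc:.4f}",
                f"template: {format_chain(ep.template_chain)}",
                f"mask: {''.join('1' if b else '0' for b in ep.feature_mask)}",
                f"selected: {' '.join(sel) if sel else '(none)'}",
                f"weights: {' '.join(f'{w:.6g}' for w in ep.weights)}",
                f"intercept: {ep.intercept:.6g}",
            ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        per = {}
        for name, ep in d["per_electrode"].items():
            y = np.asarray(ep["template_curve_y"], dtype=float)
            per[name] = ElectrodeProfile(
                electrode=name,
                template_index=int(ep["template_index"]),
                template_curve=Curve(np.arange(1, y.size + 1), y),
                template_chain=parse_chains(ep["template_chain"])[0],
                feature_mask=np.array([c == "1" for c in ep["feature_mask"]]),
                weights=np.asarray(ep["weights"], dtype=float),
                intercept=float(ep["intercept"]),
                auroc=float(ep["auroc"]),
            )
        return cls(
            status=d["status"],
            electrodes=tuple(d["electrodes"]),
            optimum_stimulations=int(d["optimum_stimulations"]),
            segments=int(d["segments"]),
            codec_mode=d.get("codec_mode", "slope"),
            per_electrode=per,
            history=d.get("history", []),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "CalibrationProfile":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _run_iteration(
    train: EpochSet, params: CalibrationParams, k: int, U: int
) -> dict:
    """One principal-wrapper iteration at stimulation count k.

    Builds O templates per electrode, runs U disjoint cross-validation folds
    per template, scores the AUROC of the distance feature, and fits the
    stepwise reduction per (electrode, template).
    """
    C = train.n_electrodes
    O = params.templates_per_electrode
    S = params.segments
    Z = np.zeros((O, C))
    banks: list[TemplateBank] = []
    stepwise_results: list[list[StepwiseResult]] = []
    matrices: dict[str, list[np.ndarray]] = {}
    for c, name in enumerate(train.electrode_names):
        ec = train.select_electrode(name)
        curves, chains, used, sw_col = [], [], [], []
        mats = []
        for o in range(O):
            ss = np.random.SeedSequence([params.master_seed, k, c, o])
            seeds = ss.spawn(1 + 2 * U)
            t_curve, t_chain, t_idx = build_template(
                ec, params.trials_per_template, S, seeds[0], params.codec_mode
            )
            rows_p, rows_n = [], []
            used_p = set(t_idx.tolist())
            used_n: set[int] = set()
            for u in range(U):
                vp, idx_p = feature_pair(
                    t_curve, t_chain, ec, P300, k, S, seeds[1 + 2 * u],
                    exclude=used_p, mode=params.codec_mode,
                )
                used_p.update(idx_p.tolist())
                vn, idx_n = feature_pair(
                    t_curve, t_chain, ec, NONP300, k, S, seeds[2 + 2 * u],
                    exclude=used_n, mode=params.codec_mode,
                )
                used_n.update(idx_n.tolist())
                rows_p.append(vp.to_array())
                rows_n.append(vn.to_array())
            Xp, Xn = np.array(rows_p), np.array(rows_n)
            Z[o, c] = auroc(Xp[:, S], Xn[:, S])  # column S+1 (1-based) is d
            X = np.vstack([Xp, Xn])
            y = np.concatenate([np.ones(U), -np.ones(U)])
            sw_col.append(stepwise_select(X, y, params.p_enter, params.p_remove))
            curves.append(t_curve)
            chains.append(t_chain)
            used.append(t_idx)
            mats.append(X)
        banks.append(TemplateBank(name, curves, chains, used))
        stepwise_results.append(sw_col)
        matrices[name] = mats
    return {
        "k": k,
        "U": U,
        "Z": Z,
        "phi": average_auroc(Z),
        "banks": banks,
        "stepwise": stepwise_results,
        "matrices": matrices,
        "electrode_names": train.electrode_names,
    }


def _profile_from_iteration(
    it: dict, selected: np.ndarray, status: str, params: CalibrationParams
) -> tuple[dict[str, ElectrodeProfile], dict[str, np.ndarray]]:
    per: dict[str, ElectrodeProfile] = {}
    mats: dict[str, np.ndarray] = {}
    for c in selected:
        name = it["electrode_names"][c]
        # ties in the argmax over templates break toward the lowest index o
        o_star = int(np.argmax(it["Z"][:, c]))
        bank: TemplateBank = it["banks"][c]
        sw: StepwiseResult = it["stepwise"][c][o_star]
        per[name] = ElectrodeProfile(
            electrode=name,
            template_index=o_star,
            template_curve=bank.curves[o_star],
            template_chain=bank.chains[o_star],
            feature_mask=sw.mask,
            weights=sw.weights,
            intercept=sw.intercept,
            auroc=float(it["Z"][o_star, c]),
        )
        mats[name] = it["matrices"][name][o_star]
    return per, mats


def calibrate(train: EpochSet, params: CalibrationParams) -> CalibrationProfile:
    """Run the principal wrapper over decreasing stimulation counts.

    Iterates k = K, K-1, ... while some electrode's mean AUROC phi clears the
    accept threshold; K' is the smallest such k (the last passing one). If no
    electrode passes at the first k, the weaker fallback threshold selects
    electrodes once and the loop stops; failing that too, the subject is
    reported unsuitable (empty electrode set, diagnostics retained).
    """
    params.validate_against(train)
    P = train.count(P300)
    N = train.count(NONP300)
    history: list[dict] = []
    last_pass: tuple[dict, np.ndarray] | None = None
    k = params.max_stimulations
    while k >= 1:
        U = n_folds(P, params.trials_per_template, k, params.max_folds)
        U = min(U, N // k)
        if U < 1:
            logger.info("calibrate: k=%d leaves no cross-validation fold; stop", k)
            break
        it = _run_iteration(train, params, k, U)
        sel, status = select_electrodes(
            it["phi"], params.auroc_accept, params.auroc_fallback
        )
        history.append(
            {
                "k": k,
                "U": U,
                "status": status,
                "phi": it["phi"],
                "Z": it["Z"],
                "electrode_names": it["electrode_names"],
            }
        )
        logger.info(
            "calibrate: k=%d U=%d status=%s phi=%s",
            k, U, status, np.round(it["phi"], 3),
        )
        if status == "accept":
            last_pass = (it, sel)
            k -= 1
            continue
        if last_pass is None:
            # first iteration already failed the accept bar
            if status == "fallback":
                per, mats = _profile_from_iteration(it, sel, status, params)
                return CalibrationProfile(
                    "fallback",
                    tuple(it["electrode_names"][c] for c in sel),
                    it["k"],
                    params.segments,
                    params.codec_mode,
                    per,
                    history,
                    mats,
                )
            return CalibrationProfile(
                "unsuitable", (), params.max_stimulations, params.segments,
                params.codec_mode, {}, history, {},
            )
        break
    if last_pass is None:
        return CalibrationProfile(
            "unsuitable", (), params.max_stimulations, params.segments,
            params.codec_mode, {}, history, {},
        )
    it, sel = last_pass
    per, mats = _profile_from_iteration(it, sel, "ok", params)
    return CalibrationProfile(
        "ok",
        tuple(it["electrode_names"][c] for c in sel),
        it["k"],
        params.segments,
        params.codec_mode,
        per,
        history,
        mats,
    )
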