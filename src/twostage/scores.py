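"""Model-agnostic model-basedness scores.

Two descriptive indices of model-based control:

* **MB-I (choice)** - the transition x reward interaction on the
  probability of repeating the previous first-stage choice:
  ``(P(stay|common,rew) - P(stay|rare,rew)) - (P(stay|common,unrew) -
  P(stay|rare,unrew))``.  A pure model-free learner shows only a reward
  main effect (score 0); a model-based learner shows a positive
  interaction.
* **MB-II (RT)** - mean second-stage RT after rare minus after common
  transitions (seconds).  A model-based learner discriminates second-stage
  values better after common transitions, hence responds faster there.

Both also come in a hierarchical flavour where the per-subject score is the
conditional (fixed + random) slope from a mixed-effects regression over the
whole cohort, with transition coded +1 common / -1 rare and reward +1 / -1.
The binary (0/1) coding of the individual score and the +/-1 coding of the
hierarchical score differ, but under both conventions positive means more
model-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .task import SessionData, pack_session

__all__ = [
    "StayTable", "ScoreSet", "stay_table", "mb1_choice", "mb2_rt",
    "score_table", "hierarchical_scores", "eta_squared",
]

#: cell order used throughout: (transition, reward) of the conditioning trial
CELL_ORDER = [("common", 1), ("common", 0), ("rare", 1), ("rare", 0)]


@dataclass
class StayTable:
    """Stay probabilities and pair counts for the four conditioning cells."""

    probs: np.ndarray   # NaN where a cell has no pairs
    counts: np.ndarray

    def cell(self, transition: str, reward: int) -> float:
        return float(self.probs[CELL_ORDER.index((transition, reward))])


@dataclass
class ScoreSet:
    """Per-subject summary row of every score variant."""

    subject_id: str
    timepoint: str
    mb1_individual: float
    mb2_individual: float
    stay_probs: np.ndarray
    stay_counts: np.ndarray
    mb1_hierarchical: float = float("nan")
    mb2_hierarchical: float = float("nan")


def _cells(session: SessionData, outcome_mask_stay=None, outcome_mask_rt=None):
    arr = pack_session(session)
    n = arr["choice1"].size
    ms = (np.ones(n, dtype=np.bool_) if outcome_mask_stay is None
          else np.asarray(outcome_mask_stay, dtype=np.bool_))
    mr = (np.ones(n, dtype=np.bool_) if outcome_mask_rt is None
          else np.asarray(outcome_mask_rt, dtype=np.bool_))
    return K.score_cells(arr["choice1"], arr["transition"], arr["reward"],
                         arr["rt2"], arr["trial"], arr["block"], ms, mr)


def stay_table(session: SessionData, outcome_mask=None) -> StayTable:
    """Stay probability conditioned on the previous trial's cell.

    A (t-1, t) pair contributes only when the two trials are consecutive
    within the same block (pairs broken by block breaks or dropped trials
    are excluded); ``outcome_mask`` restricts which *stay* trials t count
    (used by the odd/even split).  Empty cells carry NaN.
    """
    ssum, sn, _, _ = _cells(session, outcome_mask_stay=outcome_mask)
    with np.errstate(invalid="ignore"):
        probs = np.where(sn > 0, ssum / np.where(sn > 0, sn, 1), np.nan)
    return StayTable(probs=probs, counts=sn.astype(int))


def mb1_choice(session: SessionData, outcome_mask=None) -> float:
    """Transition x reward interaction on stay probability.

    NaN when any of the four cells has no pairs.
    """
    t = stay_table(session, outcome_mask)
    cr, cu, rr, ru = t.probs
    return float((cr - rr) - (cu - ru))


def mb2_rt(session: SessionData, outcome_mask=None) -> float:
    """Mean second-stage RT after rare minus after common transitions (s).

    NaN when either transition type is absent (within the mask) or RTs are
    missing.
    """
    _, _, rt_sum, rt_n = _cells(session, outcome_mask_rt=outcome_mask)
    if rt_n[0] == 0 or rt_n[1] == 0:
        return float("nan")
    return float(rt_sum[1] / rt_n[1] - rt_sum[0] / rt_n[0])


def score_table(sessions: Sequence[SessionData],
                hierarchical: bool = False) -> pd.DataFrame:
    """One row per session with all score variants and cell counts."""
    rows = []
    for s in sessions:
        t = stay_table(s)
        rows.append({
            "subject_id": s.subject_id, "timepoint": s.timepoint,
            "mb1_individual": mb1_choice(s), "mb2_individual": mb2_rt(s),
            **{f"p_stay_{tr}_{'rew' if r else 'unrew'}":
               t.cell(tr, r) for tr, r in CELL_ORDER},
            **{f"n_{tr}_{'rew' if r else 'unrew'}":
               int(t.counts[i]) for i, (tr, r) in enumerate(CELL_ORDER)},
        })
    out = pd.DataFrame(rows)
    if hierarchical:
        h = hierarchical_scores(sessions)
        out = out.merge(h, on=["subject_id", "timepoint"], how="left")
    return out


# ---------------------------------------------------------------------------
# Hierarchical (mixed-model) scores
# ---------------------------------------------------------------------------


def _long_tables(sessions, transition_sign):
    """Trial-level long tables for the two mixed models."""
    stay_rows, rt_rows = [], []
    for s in sessions:
        arr = pack_session(s)
        key = (s.subject_id, s.timepoint)
        tr = np.where(arr["transition"] == 0, 1.0, -1.0) * transition_sign
        rw = np.where(arr["reward"] == 1, 1.0, -1.0)
        c1, trial, block = arr["choice1"], arr["trial"], arr["block"]
        for t in range(arr["choice1"].size):
            if np.isfinite(arr["rt2"][t]):
                rt_rows.append((key, tr[t], arr["rt2"][t]))
            if t == 0 or block[t] != block[t - 1] or trial[t] != trial[t - 1] + 1:
                continue
            stay_rows.append((key, tr[t - 1], rw[t - 1],
                              1.0 if c1[t] == c1[t - 1] else 0.0))
    stay = pd.DataFrame(stay_rows, columns=["key", "tr", "rw", "stay"])
    rt = pd.DataFrame(rt_rows, columns=["key", "tr", "rt2"])
    return stay, rt


def hierarchical_scores(sessions: Sequence[SessionData],
                        transition_sign: float = 1.0) -> pd.DataFrame:
    """Per-subject conditional slopes from cohort-level mixed models.

    MB-I: mixed logistic regression of trial-level stay on
    transition * reward (full factorial fixed effects; independent
    per-subject random intercept and slopes, fit by variational Bayes);
    the score is the subject's conditional interaction slope.
    MB-II: linear mixed model of RT2 on transition (random intercept +
    slope); the score is the subject's conditional transition effect
    expressed, like the individual score, as rare-minus-common seconds.

    On non-convergence the individual scores are substituted with a
    warning.  ``transition_sign`` flips the +/-1 transition coding (for
    sign-convention checks).
    """
    import statsmodels.api as sm
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if len(sessions) < 2:
        raise ValueError("hierarchical scores need at least 2 subjects")
    stay, rt = _long_tables(sessions, transition_sign)
    keys = [(s.subject_id, s.timepoint) for s in sessions]
    out = pd.DataFrame({"subject_id": [k[0] for k in keys],
                        "timepoint": [k[1] for k in keys]})

    # ---- MB-I: mixed logistic, VB fit -------------------------------------
    try:
        kidx = {k: i for i, k in enumerate(keys)}
        g = stay["key"].map(kidx).to_numpy()
        nsub = len(keys)
        nrow = len(stay)
        exog = np.column_stack([np.ones(nrow), stay["tr"], stay["rw"],
                                stay["tr"] * stay["rw"]])
        # one random effect per subject for each of the four terms
        from scipy.sparse import csr_matrix
        cols = np.concatenate([g + j * nsub for j in range(4)])
        rows = np.tile(np.arange(nrow), 4)
        vals = np.concatenate([exog[:, j] for j in range(4)])
        exog_vc = csr_matrix((vals, (rows, cols)), shape=(nrow, 4 * nsub))
        ident = np.repeat(np.arange(4), nsub)
        m = BinomialBayesMixedGLM(stay["stay"].to_numpy(), exog, exog_vc,
                                  ident)
        r = m.fit_vb()
        fe_int = r.fe_mean[3]
        re_int = r.vc_mean[3 * nsub:4 * nsub]
        out["mb1_hierarchical"] = fe_int + re_int
    except Exception as e:  # pragma: no cover - defensive fallback
        warnings.warn(f"mixed logistic failed ({e}); substituting "
                      "individual MB-I scores")
        out["mb1_hierarchical"] = [mb1_choice(s) for s in sessions]

    # ---- MB-II: linear mixed model ----------------------------------------
    try:
        if rt.empty:
            raise ValueError("no RTs")
        kser = rt["key"].map({k: i for i, k in enumerate(keys)})
        exog = sm.add_constant(rt["tr"].to_numpy())
        md = sm.MixedLM(rt["rt2"].to_numpy(), exog, groups=kser.to_numpy(),
                        exog_re=exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mr = md.fit(reml=True)
        if not mr.converged:
            raise RuntimeError("MixedLM did not converge")
        fe = mr.fe_params[1]
        slopes = np.full(len(keys), np.nan)
        for gid, re in mr.random_effects.items():
            slopes[int(gid)] = fe + re.iloc[1]
        # conditional slope is per unit of the +/-1 coding; the rare-minus-
        # common difference spans 2 coded units with opposite sign
        out["mb2_hierarchical"] = -2.0 * slopes
    except Exception as e:
        warnings.warn(f"linear mixed model failed ({e}); substituting "
                      "individual MB-II scores")
        out["mb2_hierarchical"] = [mb2_rt(s) for s in sessions]
    return out


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


def eta_squared(sessions: Sequence[SessionData], score_kind: str) -> float:
    """Classical eta^2 of the condition effect on subject-level cell means.

    ``score_kind='mb1'``: share of variance of the four stay-probability
    cell means (per subject x timepoint) explained by the transition x
    reward interaction.  ``'mb2'``: share of variance of the per-condition
    mean RT2 explained by the transition main effect.  Computed as
    SS_effect / SS_total from a balanced two-way (or one-way) ANOVA over
    the cell means.
    """
    if score_kind not in ("mb1", "mb2"):
        raise ValueError("score_kind must be 'mb1' or 'mb2'")
    rows = []
    for s in sessions:
        if score_kind == "mb1":
            t = stay_table(s)
            for i, (tr, rw) in enumerate(CELL_ORDER):
                rows.append((tr, rw, t.probs[i]))
        else:
            _, _, rt_sum, rt_n = _cells(s)
            for j, tr in enumerate(("common", "rare")):
                rows.append((tr, 0, rt_sum[j] / rt_n[j] if rt_n[j] else np.nan))
    df = pd.DataFrame(rows, columns=["tr", "rw", "y"]).dropna()
    if df.empty or df["y"].var() == 0:
        return float("nan")
    y = df["y"].to_numpy()
    ss_total = np.sum((y - y.mean()) ** 2)
    if ss_total == 0:
        return float("nan")
    if score_kind == "mb2":
        eff = df.groupby("tr")["y"].transform("mean").to_numpy()
        ss_eff = np.sum((eff - y.mean()) ** 2)
    else:
        # balanced two-way decomposition: interaction = cellmean - main effects
        gm = y.mean()
        m_tr = df.groupby("tr")["y"].transform("mean").to_numpy()
        m_rw = df.groupby("rw")["y"].transform("mean").to_numpy()
        m_cell = df.groupby(["tr", "rw"])["y"].transform("mean").to_numpy()
        inter = m_cell - m_tr - m_rw + gm
        ss_eff = np.sum(inter ** 2)
    return float(ss_eff / ss_total)
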