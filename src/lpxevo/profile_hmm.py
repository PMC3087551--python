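"""Profile hidden Markov models for remote homology detection.

Plan-7-style local models (uniform begin/end linkage, N/C flank states
emitting background) built from seed alignments with Laplace-style
pseudocounts.  Scores are forward log-odds in bits against the background
residue model with a geometric length correction; E-values come from a
null tail anchored to forward scores of random sequences, scaled by a
constant trial count of 20,000 candidate sequences per genome-equivalent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


from ._kernels import hmm_forward, hmm_forward_batch, hmm_viterbi
from .pairwise_search import ALPHABET, BACKGROUND, Hit, encode

N_TRIALS = 20_000  # constant sample size: candidate sequences per search
EXIT_PROB = 0.01   # per-match-state probability of leaving to the end state
TAIL_MASS = 0.05   # calibration quantile anchoring the null tail


@dataclass
class ProfileHMM:
    match_emissions: np.ndarray       # (M+1, 20), row 0 unused
    t: Dict[str, np.ndarray]          # MM, MI, MD, IM, II, DM, DD arrays (M+1)
    entry: np.ndarray                 # (M+1,) B->Mj
    exit: np.ndarray                  # (M+1,) Mj->E
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    calibration: Optional["HmmCalibration"] = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0] - 1

    def validate(self) -> None:
        M = self.length
        if M < 1:
            raise ValueError("model length must be >= 1")
        for j in range(1, M + 1):
            if abs(self.match_emissions[j].sum() - 1.0) > 1e-9:
                raise ValueError(f"match emissions at column {j} do not sum to 1")
            out = self.t["MM"][j] + self.t["MI"][j] + self.t["MD"][j] + self.exit[j]
            if abs(out - 1.0) > 1e-9:
                raise ValueError(f"match transitions at column {j} do not sum to 1")
            if abs(self.t["IM"][j] + self.t["II"][j] - 1.0) > 1e-9:
                raise ValueError(f"insert transitions at column {j} do not sum to 1")
            if abs(self.t["DM"][j] + self.t["DD"][j] - 1.0) > 1e-9:
                raise ValueError(f"delete transitions at column {j} do not sum to 1")
        if abs(self.entry[1:].sum() - 1.0) > 1e-9:
            raise ValueError("entry distribution does not sum to 1")

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "alphabet": ALPHABET,
            "match_emissions": self.match_emissions.tolist(),
            "transitions": {k: v.tolist() for k, v in self.t.items()},
            "entry": self.entry.tolist(),
            "exit": self.exit.tolist(),
            "background": self.background.tolist(),
            "calibration": None
            if self.calibration is None
            else {
                "mu": self.calibration.mu,
                "beta": self.calibration.beta,
                "n_samples": self.calibration.n_samples,
                "seed": self.calibration.seed,
            },
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        obj = json.loads(text)
        hmm = cls(
            match_emissions=np.array(obj["match_emissions"]),
            t={k: np.array(v) for k, v in obj["transitions"].items()},
            entry=np.array(obj["entry"]),
            exit=np.array(obj["exit"]),
            background=np.array(obj["background"]),
        )
        cal = obj.get("calibration")
        if cal:
            hmm.calibration = HmmCalibration(cal["mu"], cal["beta"], cal["n_samples"], cal["seed"])
        return hmm


@dataclass
class HmmCalibration:
    mu: float
    beta: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("Gumbel scale must be positive")


def build_hmm(
    seed_alignment: Sequence[Tuple[str, str]],
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    transition_pseudocount: float = 0.1,
) -> ProfileHMM:
    """Build a profile from a gapped seed alignment.

    Columns whose residue occupancy is >= `occupancy_threshold` become match
    states.  Emissions get a fixed-weight background pseudocount (a
    Laplace-style prior, not Dirichlet mixtures); transitions get a much
    lighter one — a heavy transition prior would tax every match->match
    step and cripple remote detection on long models.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs >= 2 rows")
    rows = [s.upper() for _, s in seed_alignment]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    n = len(rows)
    occ = np.array([sum(1 for r in rows if r[c] not in "-.") / n for c in range(ncol)])
    match_cols = [c for c in range(ncol) if occ[c] >= occupancy_threshold]
    if not match_cols:
        raise ValueError("no columns pass the occupancy threshold (all-gap alignment?)")
    M = len(match_cols)
    code = {a: i for i, a in enumerate(ALPHABET)}

    emis = np.zeros((M + 1, 20))
    for j, c in enumerate(match_cols, start=1):
        counts = np.zeros(20)
        for r in rows:
            ch = r[c]
            if ch in code:
                counts[code[ch]] += 1.0
        # total pseudo-mass pw*20, spread as the background (Laplace-style)
        emis[j] = counts + pseudocount_weight * 20.0 * BACKGROUND
        emis[j] /= emis[j].sum()

    # transition counts from each row's path through the match-column skeleton
    tc = {k: np.zeros(M + 1) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}
    match_set = set(match_cols)
    for r in rows:
        state, idx = "M", 0  # position 0 = begin, treated as a match column
        for c in range(ncol):
            is_match_col = c in match_set
            resident = r[c] not in "-."
            if is_match_col:
                new_state = "M" if resident else "D"
                if state + new_state in tc:  # Plan-7 has no I->D edge
                    tc[state + new_state][idx] += 1
                state, idx = new_state, idx + 1
            elif resident and state != "D":
                # inserts hanging off a delete state have no Plan-7 edge
                tc[state + "I"][idx] += 1
                state = "I"
    pw = transition_pseudocount
    t = {k: np.zeros(M + 1) for k in tc}
    for j in range(M + 1):
        m_tot = tc["MM"][j] + tc["MI"][j] + tc["MD"][j] + 3 * pw
        t["MM"][j] = (tc["MM"][j] + pw) / m_tot
        t["MI"][j] = (tc["MI"][j] + pw) / m_tot
        t["MD"][j] = (tc["MD"][j] + pw) / m_tot
        i_tot = tc["IM"][j] + tc["II"][j] + 2 * pw
        t["IM"][j] = (tc["IM"][j] + pw) / i_tot
        t["II"][j] = (tc["II"][j] + pw) / i_tot
        d_tot = tc["DM"][j] + tc["DD"][j] + 2 * pw
        t["DM"][j] = (tc["DM"][j] + pw) / d_tot
        t["DD"][j] = (tc["DD"][j] + pw) / d_tot
    # reserve a uniform exit probability from each match state; last column
    # always exits
    exit_ = np.zeros(M + 1)
    for j in range(1, M + 1):
        if j == M:
            exit_[j] = 1.0
            t["MM"][j] = t["MI"][j] = t["MD"][j] = 0.0
        else:
            exit_[j] = EXIT_PROB
            for k in ("MM", "MI", "MD"):
                t[k][j] *= 1.0 - EXIT_PROB
    entry = np.zeros(M + 1)
    entry[1:] = 1.0 / M
    hmm = ProfileHMM(match_emissions=emis, t=t, entry=entry, exit=exit_)
    hmm.validate()
    return hmm


def _flank_r(L: int) -> float:
    return L / (L + 1.0)


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Forward log-odds score in bits (local alignment vs background)."""
    if not seq:
        raise ValueError("empty sequence")
    x = encode(seq)
    x = np.where(x == 20, 0, x)  # X scored as Ala-vs-background (odds ~1)
    odds = hmm.match_emissions / hmm.background
    nats = hmm_forward(
        x, odds, hmm.t["MM"], hmm.t["MI"], hmm.t["MD"], hmm.t["IM"],
        hmm.t["II"], hmm.t["DM"], hmm.t["DD"], hmm.entry, hmm.exit,
        _flank_r(len(x)),
    )
    return nats / math.log(2.0)


def forward_scores_encoded(hmm: ProfileHMM, xcat: np.ndarray,
                           offsets: np.ndarray) -> np.ndarray:
    """Forward bit scores for many pre-encoded sequences (codes 0-19,
    concatenated; ``offsets`` delimits them).  One kernel call — use this
    for large searches."""
    odds = hmm.match_emissions / hmm.background
    nats = hmm_forward_batch(
        xcat, offsets.astype(np.int64), odds,
        hmm.t["MM"], hmm.t["MI"], hmm.t["MD"], hmm.t["IM"], hmm.t["II"],
        hmm.t["DM"], hmm.t["DD"], hmm.entry, hmm.exit,
    )
    return nats / math.log(2.0)


def viterbi_score(hmm: ProfileHMM, seq: str) -> Tuple[float, int, int, int, int]:
    """Best-path score (bits) and its (qstart, qend, mstart, mend) interval."""
    x = encode(seq)
    x = np.where(x == 20, 0, x)
    with np.errstate(divide="ignore"):
        lodds = np.log(hmm.match_emissions / hmm.background)
        largs = [np.log(hmm.t[k]) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")]
        lentry = np.log(hmm.entry)
        lexit = np.log(hmm.exit)
    r = _flank_r(len(x))
    nats, q0, q1, j0, j1 = hmm_viterbi(
        x, lodds, *largs, lentry, lexit, math.log(r), math.log(1 - r)
    )
    return nats / math.log(2.0), int(q0), int(q1), int(j0), int(j1)


def calibrate(
    hmm: ProfileHMM,
    n_random: int = 1000,
    bg: Optional[np.ndarray] = None,
    seed: int = 0,
    length: Optional[int] = None,
) -> HmmCalibration:
    """Fit a Gumbel to forward scores of random background sequences.

    E-values are then ``N_TRIALS * P(score >= S)`` under the fitted Gumbel.
    """
    if n_random < 500:
        raise ValueError("n_random must be >= 500")
    bg = BACKGROUND if bg is None else bg
    L = length or max(hmm.length, 30)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for i in range(n_random):
        s = "".join(ALPHABET[k] for k in rng.choice(20, size=L, p=bg))
        scores[i] = forward_score(hmm, s)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate calibration score distribution")
    # Forward-score nulls have an exponential right tail whose slope
    # approaches ln 2 per bit (the Chernoff bound P(S >= s) <= 2^-s).  A
    # maximum-likelihood Gumbel badly underestimates that tail, so the fit
    # anchors the Gumbel tail at the empirical TAIL_MASS quantile with the
    # conservative asymptotic slope.
    lam = math.log(2.0)
    s0 = float(np.quantile(scores, 1.0 - TAIL_MASS))
    mu = s0 + math.log(TAIL_MASS) / lam
    cal = HmmCalibration(mu, 1.0 / lam, n_random, seed)
    hmm.calibration = cal
    return cal


def hmm_evalue(hmm: ProfileHMM, score_bits) -> float:
    """E = 20,000-trial scaling of the fitted Gumbel tail (vectorises)."""
    if hmm.calibration is None:
        raise ValueError("model is not calibrated")
    c = hmm.calibration
    z = (np.asarray(score_bits, dtype=float) - c.mu) / c.beta
    p = -np.expm1(-np.exp(-z))
    out = N_TRIALS * p
    return float(out) if out.ndim == 0 else out


def hmm_search(
    hmm: ProfileHMM,
    proteome: Sequence[Tuple[str, str]],
    cutoff: float = 0.01,
    query_id: str = "hmm",
) -> List[Hit]:
    """All proteome members with forward E-value <= cutoff, best first.

    Hit intervals come from the Viterbi path; bit score is the forward score.
    """
    if hmm.calibration is None:
        raise ValueError("model is not calibrated")
    codes = [np.where(encode(s) == 20, 0, encode(s)) for _, s in proteome]
    offsets = np.zeros(len(codes) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(c) for c in codes])
    xcat = np.concatenate(codes) if codes else np.zeros(0, dtype=np.int64)
    scores = forward_scores_encoded(hmm, xcat, offsets)
    evalues = hmm_evalue(hmm, scores)
    hits: List[Hit] = []
    for (tid, tseq), s, ev in zip(proteome, scores, np.atleast_1d(evalues)):
        if ev <= cutoff:
            _, q0, q1, j0, j1 = viterbi_score(hmm, tseq)
            hits.append(Hit(query_id, tid, float(s), float(s), float(ev), j0, j1, q0, q1))
    hits.sort(key=lambda h: (h.evalue, -h.bits, h.target))
    return hits
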