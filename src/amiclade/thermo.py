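"""Guide:target duplex evaluation.

The silencing efficacy proxy used throughout the design is the *energy
fraction*: the predicted hybridization free energy of the 21-nt guide
(mature, antisense) against a candidate target site, divided by the free
energy of the guide against its perfect reverse complement.  A perfect site
has fraction 1; mismatches and G:U wobbles raise the duplex energy (make it
less negative) and push the fraction toward 0.  A gene is an *effective
target* when its best site both clears the fraction threshold omega and
satisfies positional mismatch-admissibility rules.

The energy model is a simplified nearest-neighbor scheme: published RNA/RNA
stacking free energies for adjacent Watson-Crick pairs, a duplex initiation
term, and flat positive penalties for each internal mismatch or G:U wobble
(wobbles and mismatches interrupt stacking).  Parameters live in a packaged
data table and are fully user-overridable; dangling ends and terminal-
mismatch corrections are deliberately omitted as second-order relative to
the fraction threshold.

Pairing geometry: the guide anneals antiparallel to the sense-strand site,
so guide position 1 (5' end) pairs with site position 21.  All reported
positions are 1-based from the guide 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


class ThermoError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Encode ACGT to int8 codes (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ThermoError(f"non-ACGT character {exc} in sequence") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[c] for c in codes)


@dataclass(frozen=True)
class AdmissibilityRules:
    """Positional mismatch rules for a workable guide:site hybrid.

    Positions are 1-based from the guide 5' end.  Defaults render the
    classic plant-amiRNA target rules: the cleavage-site positions 10-11
    must pair perfectly (no mismatch, no wobble), the 5' seed-proximal
    region 2-9 tolerates at most one mismatch, the 3' region 12-21 at most
    three, and at most four mismatch-equivalents total, a G:U wobble
    counting as half a mismatch (totals rounded up).  Position 1 is left
    unconstrained (beyond the total) because the engineered 5'-U edit of
    candidate guides routinely mismatches there.
    """

    perfect_positions: tuple[int, int] = (10, 11)
    seed_region: tuple[int, int] = (2, 9)
    seed_max_mismatches: int = 1
    tail_region: tuple[int, int] = (12, 21)
    tail_max_mismatches: int = 3
    max_total: int = 4
    gu_counts_half: bool = True


DEFAULT_RULES = AdmissibilityRules()


@dataclass
class DuplexModel:
    """Nearest-neighbor duplex energy model (kcal/mol).

    ``stack[a, b]`` is the stacking free energy of the guide dinucleotide
    step a->b (5'->3') over its Watson-Crick partner; negative values
    stabilize.  ``mismatch_penalty`` and ``gu_penalty`` are flat positive
    increments per non-paired / wobble position.
    """

    stack: np.ndarray  # (4, 4) float
    mismatch_penalty: float
    gu_penalty: float
    init_energy: float
    rules: AdmissibilityRules = field(default_factory=AdmissibilityRules)

    def __post_init__(self) -> None:
        if not np.all(self.stack < 0):
            raise ThermoError("all Watson-Crick stack values must be < 0")
        if self.mismatch_penalty <= 0 or self.gu_penalty <= 0:
            raise ThermoError("penalties must be > 0")
        if self.gu_penalty >= self.mismatch_penalty:
            raise ThermoError("gu_penalty must be < mismatch_penalty")


def load_model(
    path: str | Path | None = None,
    rules: AdmissibilityRules | None = None,
) -> DuplexModel:
    """Load the duplex model from a TSV table (default: packaged table)."""
    if path is None:
        res = resources.files("amiclade.data").joinpath("nn_rna.tsv")
        with resources.as_file(res) as p:
            return load_model(p, rules)
    stack = np.full((4, 4), np.nan)
    special: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")
            if key in ("INIT", "MISMATCH", "GU"):
                special[key] = float(val)
            else:
                stack[_BASE_CODE[key[0]], _BASE_CODE[key[1]]] = float(val)
    if np.isnan(stack).any() or len(special) != 3:
        raise ThermoError(f"incomplete nearest-neighbor table {path}")
    return DuplexModel(
        stack=stack,
        mismatch_penalty=special["MISMATCH"],
        gu_penalty=special["GU"],
        init_energy=special["INIT"],
        rules=rules or DEFAULT_RULES,
    )


@dataclass(frozen=True)
class HybridEvaluation:
    """Outcome of evaluating one guide against one 21-nt site."""

    delta_g: float
    fraction: float
    mismatch_positions: tuple[int, ...]  # 1-based from guide 5' end
    gu_positions: tuple[int, ...]
    admissible: bool


# ---------------------------------------------------------------------------
# core energy computation (vectorized over windows)


def _pair_status(
    mature_codes: np.ndarray, sites_rev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """WC / GU boolean masks for guide vs reversed site codes.

    ``sites_rev`` has the site read 3'->5' so index i faces guide index i.
    Shapes broadcast: mature (L,), sites_rev (..., L).
    """
    comp = 3 - mature_codes  # A<->T, C<->G under the 0..3 encoding
    wc = sites_rev == comp
    m = mature_codes
    gu = ((m == 2) & (sites_rev == 3)) | ((m == 3) & (sites_rev == 2))
    gu = gu & ~wc
    return wc, gu


def _energies(
    model: DuplexModel, mature_codes: np.ndarray, windows: np.ndarray
) -> np.ndarray:
    """Duplex ΔG of one guide vs many sense-strand windows, shape (n,)."""
    rev = windows[:, ::-1]
    wc, gu = _pair_status(mature_codes, rev)
    mm = ~wc & ~gu
    stack_vals = model.stack[mature_codes[:-1], mature_codes[1:]]
    stacked = wc[:, :-1] & wc[:, 1:]
    return (
        model.init_energy
        + stacked @ stack_vals
        + model.mismatch_penalty * mm.sum(axis=1)
        + model.gu_penalty * gu.sum(axis=1)
    )


def perfect_match_energy(model: DuplexModel, mature: str) -> float:
    """ΔG of the guide against its exact reverse complement."""
    codes = encode(mature)
    stack_vals = model.stack[codes[:-1], codes[1:]]
    dg = model.init_energy + stack_vals.sum()
    if dg >= 0:
        raise ThermoError(
            f"perfect-match energy non-negative for {mature!r}; "
            "pathological composition"
        )
    return float(dg)


def duplex_energy(model: DuplexModel, mature: str, site: str) -> float:
    """ΔG (kcal/mol) of a guide hybridized to a sense-strand site."""
    if len(mature) != len(site):
        raise ThermoError(
            f"length mismatch: mature {len(mature)} vs site {len(site)}"
        )
    m = encode(mature)
    w = encode(site)[None, :]
    return float(_energies(model, m, w)[0])


def energy_fraction(model: DuplexModel, mature: str, site: str) -> HybridEvaluation:
    """Evaluate one guide:site pair: ΔG, fraction of perfect, admissibility."""
    if len(mature) != len(site):
        raise ThermoError(
            f"length mismatch: mature {len(mature)} vs site {len(site)}"
        )
    m = encode(mature)
    rev = encode(site)[::-1]
    wc, gu = _pair_status(m, rev[None, :])
    wc, gu = wc[0], gu[0]
    dg = float(_energies(model, m, encode(site)[None, :])[0])
    dg_perfect = perfect_match_energy(model, mature)
    if wc.all():  # perfect reverse complement: fraction is exactly 1
        fraction = 1.0
    else:
        fraction = dg / dg_perfect
    if fraction < 0.0:
        logger.debug("fraction clipped to 0 for %s vs %s", mature, site)
        fraction = 0.0
    elif fraction > 1.0:
        logger.debug("fraction clipped to 1 for %s vs %s", mature, site)
        fraction = 1.0
    mm_pos = tuple(int(i) + 1 for i in np.nonzero(~wc & ~gu)[0])
    gu_pos = tuple(int(i) + 1 for i in np.nonzero(gu)[0])
    ev = HybridEvaluation(
        delta_g=dg,
        fraction=fraction,
        mismatch_positions=mm_pos,
        gu_positions=gu_pos,
        admissible=False,
    )
    return HybridEvaluation(
        **{**ev.__dict__, "admissible": admissible_hybrid(ev, model.rules)}
    )


def admissible_hybrid(
    evaluation: HybridEvaluation, rules: AdmissibilityRules = DEFAULT_RULES
) -> bool:
    """Apply the positional mismatch rules to an evaluated hybrid."""
    mm = set(evaluation.mismatch_positions)
    gu = set(evaluation.gu_positions)
    lo, hi = rules.perfect_positions
    if any(lo <= p <= hi for p in mm | gu):
        return False
    lo, hi = rules.seed_region
    if sum(1 for p in mm if lo <= p <= hi) > rules.seed_max_mismatches:
        return False
    lo, hi = rules.tail_region
    if sum(1 for p in mm if lo <= p <= hi) > rules.tail_max_mismatches:
        return False
    if rules.gu_counts_half:
        total = int(np.ceil(len(mm) + 0.5 * len(gu)))
    else:
        total = len(mm) + len(gu)
    return total <= rules.max_total


def best_site(
    model: DuplexModel, mature: str, transcript: str
) -> tuple[HybridEvaluation, tuple[int, int]]:
    """Best (maximal-fraction) sense-strand site of a guide on a transcript.

    Scans every window with step 1; ties broken by smallest start.  Returns
    the evaluation and 0-based half-open coordinates of the winning window.
    """
    L = len(mature)
    if len(transcript) < L:
        raise ThermoError("transcript shorter than the mature length")
    m = encode(mature)
    t = encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    dg = _energies(model, m, windows)
    start = int(np.argmin(dg))  # most negative ΔG = highest fraction
    site = transcript[start : start + L]
    return energy_fraction(model, mature, site), (start, start + L)


def best_sites_batch(
    model: DuplexModel, matures: list[str], transcript: str, chunk: int = 256
) -> list[tuple[HybridEvaluation, tuple[int, int]]]:
    """Vectorized :func:`best_site` for many guides on one transcript.

    Equivalent to ``[best_site(model, m, transcript) for m in matures]`` but
    evaluates the ΔG of all windows for a chunk of guides in one pass.
    """
    L = len(matures[0]) if matures else 0
    if len(transcript) < L:
        raise ThermoError("transcript shorter than the mature length")
    t = encode(transcript)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)  # (n, L)
    rev = windows[:, ::-1]
    out: list[tuple[HybridEvaluation, tuple[int, int]]] = []
    stack = model.stack
    for lo in range(0, len(matures), chunk):
        block = matures[lo : lo + chunk]
        M = np.array([[_BASE_CODE[b] for b in s] for s in block], dtype=np.int8)
        comp = 3 - M  # (k, L)
        wc = rev[None, :, :] == comp[:, None, :]  # (k, n, L)
        gu = (
            ((M[:, None, :] == 2) & (rev[None, :, :] == 3))
            | ((M[:, None, :] == 3) & (rev[None, :, :] == 2))
        ) & ~wc
        mm = ~wc & ~gu
        stack_vals = stack[M[:, :-1], M[:, 1:]]  # (k, L-1)
        stacked = wc[:, :, :-1] & wc[:, :, 1:]
        dg = (
            model.init_energy
            + np.einsum("knl,kl->kn", stacked, stack_vals)
            + model.mismatch_penalty * mm.sum(axis=2)
            + model.gu_penalty * gu.sum(axis=2)
        )
        starts = np.argmin(dg, axis=1)
        for s, mat in zip(starts, block):
            site = transcript[int(s) : int(s) + L]
            out.append((energy_fraction(model, mat, site), (int(s), int(s) + L)))
    return out
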