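"""Classify genotypes into named strategy categories.

A genotype's likely response to each prisoner's-dilemma outcome (R, T, P,
S), starting from a stated prior emotional state, is one of Coop, Def or
Div: divorce if the updated attachment s_a' <= 0, cooperate if s_a' > 0
and the updated cooperativeness s_c' > 0, defect otherwise.  The pattern
of four responses is matched against the category table:

    Cooperator      C C C C       always cooperates
    No S            C C C d       cooperates except on S
    Reciprocator    C C d .       Tit-For-Tat-like (generous if S=Coop)
    WSLS-like       C d C .       Win-Stay/Lose-Shift-like
    Trigger         C d d .       cooperates only after R
    Opportunist     D  Coop on >=1 of T,P    exploits generous cooperators
    Quitter         V  Coop on >=1 of T,P    divorces on mutual cooperation
    Defector        no cooperation on R, T or P

(C=Coop, d=Def or Div, D=Def, V=Div; '.' fixes generosity: the generous
variant cooperates on S.)  Matching precedence is Quitter, Defector,
Opportunist, then the exact rows, which maps each of the 81 possible
response patterns to exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    E_ATT,
    E_COOP,
    OUTCOMES,
    Genotype,
    emotion_without_bookkeeping,
    update_emotion,
)

__all__ = [
    "COOP",
    "DEF",
    "DIV",
    "CATEGORIES",
    "PriorEmotion",
    "StrategyLabel",
    "response_to",
    "response_pattern",
    "label_from_responses",
    "classify",
    "prevalence",
    "classify_genotype_table",
]

COOP, DEF, DIV = "Coop", "Def", "Div"

CATEGORIES = (
    "Cooperator",
    "No S",
    "Reciprocator",
    "WSLS-like",
    "Trigger",
    "Opportunist",
    "Quitter",
    "Defector",
)

# categories whose S response is fixed by the table (no generous variant)
_NO_GENEROUS = {"Cooperator", "No S", "Quitter", "Defector"}


@dataclass(frozen=True)
class PriorEmotion:
    """Prior (cooperativeness, attachment) state at which to classify."""

    s_c: float
    s_a: float
    name: str = ""

    @classmethod
    def presets(cls) -> dict[str, "PriorEmotion"]:
        # the negative attachment prior is -0.5: anything lower would have
        # deterministically divorced in the previous iteration
        return {
            "negative": cls(s_c=-1.0, s_a=-0.5, name="negative"),
            "neutral": cls(s_c=0.0, s_a=0.0, name="neutral"),
            "positive": cls(s_c=1.0, s_a=1.0, name="positive"),
        }


@dataclass(frozen=True)
class StrategyLabel:
    category: str
    generous: bool = False

    def __str__(self) -> str:
        return f"Generous {self.category}" if self.generous else self.category


def response_to(g: Genotype, prior: PriorEmotion, outcome: str,
                bookkeeping: bool = True) -> str:
    """Likely action (Coop/Def/Div) after one outcome from the prior state."""
    code = OUTCOMES.index(outcome)
    if bookkeeping:
        s_a = update_emotion(prior.s_a, g["ab"], g["av"], g.response(E_ATT, code))
        s_c = update_emotion(prior.s_c, g["cb"], g["cv"], g.response(E_COOP, code))
    else:
        s_a = emotion_without_bookkeeping(g, E_ATT, code)
        s_c = emotion_without_bookkeeping(g, E_COOP, code)
    if s_a <= 0:
        return DIV
    return COOP if s_c > 0 else DEF


def response_pattern(g: Genotype, prior: PriorEmotion,
                     bookkeeping: bool = True) -> tuple[str, str, str, str]:
    """Responses to (R, T, P, S), in that order."""
    return tuple(response_to(g, prior, o, bookkeeping) for o in ("R", "T", "P", "S"))


def label_from_responses(responses: Sequence[str]) -> StrategyLabel:
    """Map a (R, T, P, S) response pattern to its strategy category."""
    r, t, p, s = responses
    for x in responses:
        if x not in (COOP, DEF, DIV):
            raise ValueError(f"unknown response {x!r}")
    coop_tp = COOP in (t, p)
    generous_s = s == COOP

    if r == DIV and coop_tp:
        return StrategyLabel("Quitter")
    if r != COOP and not coop_tp:
        return StrategyLabel("Defector")
    if r == DEF and coop_tp:
        return StrategyLabel("Opportunist", generous=generous_s)

    # r == Coop from here; Div and Def are interchangeable ("d")
    if t == COOP and p == COOP:
        return StrategyLabel("Cooperator") if generous_s else StrategyLabel("No S")
    if t == COOP:
        return StrategyLabel("Reciprocator", generous=generous_s)
    if p == COOP:
        return StrategyLabel("WSLS-like", generous=generous_s)
    return StrategyLabel("Trigger", generous=generous_s)


def classify(g: Genotype, prior: PriorEmotion, bookkeeping: bool = True) -> StrategyLabel:
    """Classify one genotype at one prior emotional state."""
    return label_from_responses(response_pattern(g, prior, bookkeeping))


def prevalence(genotypes: Iterable[Genotype], priors: Sequence[PriorEmotion],
               bookkeeping: bool = True) -> pd.DataFrame:
    """Category fractions per prior state over a population of genotypes.

    Returns a tidy frame (prior, category, generous, fraction); fractions
    sum to one within each prior.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("prevalence of an empty population is undefined")
    rows = []
    for prior in priors:
        counts: dict[tuple[str, bool], int] = {}
        for g in genotypes:
            lab = classify(g, prior, bookkeeping)
            counts[(lab.category, lab.generous)] = counts.get((lab.category, lab.generous), 0) + 1
        for (cat, gen), c in sorted(counts.items()):
            rows.append({
                "prior": prior.name or f"({prior.s_c},{prior.s_a})",
                "category": cat,
                "generous": gen,
                "fraction": c / len(genotypes),
            })
    return pd.DataFrame(rows, columns=["prior", "category", "generous", "fraction"])


def classify_genotype_table(path_or_df, priors: Sequence[PriorEmotion] | None = None,
                            bookkeeping: bool = True, condition: str = "",
                            out_csv: str | Path | None = None) -> pd.DataFrame:
    """Classify a final-genotype CSV (as written by the runner) per prior state."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    from .core import EMOTIONS, TRAIT_NAMES

    cols = [f"G_{e}{t}" for e in EMOTIONS for t in TRAIT_NAMES]
    geno = df[cols].to_numpy(dtype=float).reshape(-1, 4, 6)
    genotypes = [Genotype(geno[i]) for i in range(geno.shape[0])]
    if priors is None:
        priors = list(PriorEmotion.presets().values())
    table = prevalence(genotypes, priors, bookkeeping)
    table.insert(0, "condition", condition)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
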