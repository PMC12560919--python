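"""Shared test utilities: independent brute-force oracles and generators.

The oracles transcribe the index formulas directly from their
definitions, with literal dictionary access and no shared code with the
implementation, so that implementation/oracle agreement is a real
cross-check.
"""

from __future__ import annotations

import numpy as np

from nutriscore.types import CANONICAL_FATTY_ACIDS, FattyAcidProfile

PANEL = list(CANONICAL_FATTY_ACIDS)


def random_profile(rng: np.random.Generator, scale: float = 3.0) -> FattyAcidProfile:
    """A random full-panel profile with every acid strictly positive."""
    vals = rng.uniform(0.05, scale, size=len(PANEL))
    return FattyAcidProfile(dict(zip(PANEL, vals)))


# --- brute-force transcriptions of the index definitions -------------------


def oracle_classes(v: dict[str, float], as_published: bool = True) -> dict[str, float]:
    sfa = (
        v["C10:0"] + v["C12:0"] + v["C14:0"] + v["C15:0"]
        + v["C16:0"] + v["C17:0"] + v["C18:0"] + v["C20:0"]
    )
    mufa = v["C14:1"] + v["C16:1"] + v["C18:1 cis"] + v["C20:1"]
    pufa = v["C18:2 cis"] + v["C18:3 cis n3"]
    n3 = v["C18:3 cis n3"]
    n6 = v["C18:2 cis"] + (v["C18:2 trans"] if as_published else 0.0)
    return {
        "sfa": sfa,
        "mufa": mufa,
        "pufa": pufa,
        "ufa": mufa + pufa,
        "tfa": v["C18:1 trans"] + v["C18:2 trans"],
        "n3": n3,
        "n6": n6,
    }


def oracle_ai(v: dict[str, float], as_published: bool = True) -> float:
    c = oracle_classes(v, as_published)
    return (v["C12:0"] + v["C16:0"] + 4.0 * v["C14:0"]) / (
        c["mufa"] + c["n6"] + c["n3"]
    )


def oracle_ti(v: dict[str, float], as_published: bool = True) -> float:
    c = oracle_classes(v, as_published)
    return (v["C14:0"] + v["C16:0"] + v["C18:0"]) / (
        0.5 * c["mufa"] + 0.5 * c["n6"] + 3.0 * c["n3"] + c["n3"] / c["n6"]
    )


def oracle_hh(v: dict[str, float], as_published: bool = True) -> float:
    c181 = v["C18:1 trans"] if as_published else v["C18:1 cis"]
    return (c181 + v["C18:2 cis"] + v["C18:3 cis n3"]) / (
        v["C12:0"] + v["C14:0"] + v["C16:0"]
    )


def oracle_eaai_direct(scores: dict[str, float]) -> float:
    """Direct n-th-root-of-product geometric mean (no log transform)."""
    prod = 1.0
    for s in scores.values():
        prod *= s
    return prod ** (1.0 / len(scores))
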