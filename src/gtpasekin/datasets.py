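"""Packaged reference rate constants for TTN5 and loaders over them."""

from __future__ import annotations

import json
from importlib import resources

from .cycle import CycleParameters
from .fitting import NucleotideKinetics

_RATES_FILE = "ttn5_printed_rates.json"


def load_printed_rates() -> dict:
    """Load the packaged table of published TTN5 rate constants."""
    ref = resources.files("gtpasekin.data").joinpath(_RATES_FILE)
    return json.loads(ref.read_text())


def kinetics_entries(rates: dict | None = None):
    """Turn the packaged rates into (entries, k_cat map) for the table builder."""
    rates = rates or load_printed_rates()
    entries: list[NucleotideKinetics] = []
    kcat: dict[str, float] = {}
    for variant, rec in rates["variants"].items():
        kcat[variant] = rec["k_cat"]
        for nuc in ("GDP", "GppNHp"):
            if nuc not in rec:
                continue
            entries.append(
                NucleotideKinetics.from_rates(
                    variant, nuc, rec[nuc]["k_on"], rec[nuc]["k_off"]
                )
            )
    return entries, kcat


def reported_kd_map(rates: dict | None = None) -> dict[tuple[str, str], float]:
    """The source's own K_d table, keyed by (variant, nucleotide).

    These were computed from unrounded rates before printing, so ratios
    formed from them are more faithful than ratios of re-derived
    k_off/k_on quotients of the rounded rates.
    """
    rates = rates or load_printed_rates()
    return {
        (variant, nuc): kd
        for variant, per_nuc in rates.get("printed_Kd_uM", {}).items()
        for nuc, kd in per_nuc.items()
    }


def cycle_parameters(variant: str = "WT", rates: dict | None = None) -> CycleParameters:
    """Five-constant cycle parameter set for one variant.

    Requires a measured k_on for both nucleotides, so it is unavailable
    for T30N (no observed GppNHp association).
    """
    rates = rates or load_printed_rates()
    rec = rates["variants"][variant]
    if rec["GDP"]["k_on"] is None or rec["GppNHp"]["k_on"] is None:
        raise KeyError(f"variant {variant!r} lacks a measured k_on for both nucleotides")
    return CycleParameters(
        k_on_GDP=rec["GDP"]["k_on"],
        k_off_GDP=rec["GDP"]["k_off"],
        k_on_GTP=rec["GppNHp"]["k_on"],
        k_off_GTP=rec["GppNHp"]["k_off"],
        k_cat=rec["k_cat"],
    )
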