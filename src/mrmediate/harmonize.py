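"""Allele harmonization between two GWAS summary datasets.

Two-sample MR requires the SNP-outcome effect to be expressed for the
same effect allele as the SNP-exposure effect.  Alleles may be recorded
swapped (effect/other exchanged) or on the opposite strand; palindromic
A/T and C/G variants cannot be strand-resolved from the alleles alone
and are disambiguated by allele frequency or dropped when the frequency
is too close to 0.5 to be informative.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import AssocRecord, HarmonizedSet, SummaryDataset, complement


class HarmonizationError(ValueError):
    pass


DEFAULT_PALINDROME_EAF_WINDOW = 0.08


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Parameters
    ----------
    exposure, outcome
        Summary datasets for the two traits; ``outcome`` may equally be a
        mediator dataset.
    palindrome_eaf_window
        Half-width of the effect-allele-frequency band around 0.5 inside
        which a palindromic SNP is considered strand-ambiguous and
        dropped; must lie in [0, 0.5).

    Returns
    -------
    HarmonizedSet
        Retained SNPs with ``beta_y`` expressed for the exposure's effect
        allele, plus reason codes for every dropped SNP.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise HarmonizationError("no_overlap: empty input dataset")
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")

    dropped: dict[str, str] = {}
    rows = []
    shared = 0
    for rx in exposure.records:
        if rx.snp_id not in outcome:
            dropped[rx.snp_id] = "missing_in_other_dataset"
            continue
        shared += 1
        ry = _orient(rx, outcome.get(rx.snp_id), palindrome_eaf_window, dropped)
        if ry is None:
            continue
        rows.append(
            {
                "snp_id": rx.snp_id,
                "beta_x": rx.beta,
                "se_x": rx.se,
                "beta_y": ry.beta,
                "se_y": ry.se,
            }
        )
    if shared == 0:
        raise HarmonizationError("no_overlap: no shared snp_id between datasets")

    return HarmonizedSet(
        table=pd.DataFrame(rows, columns=["snp_id", "beta_x", "se_x", "beta_y", "se_y"]),
        dropped=dropped,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        binary_outcome=outcome.binary_outcome,
    )


def _orient(
    rx: AssocRecord,
    ry: AssocRecord,
    window: float,
    dropped: dict[str, str],
) -> AssocRecord | None:
    """Return the outcome record expressed for rx's effect allele, or None."""
    ea, oa = rx.effect_allele.upper(), rx.other_allele.upper()
    ea2, oa2 = ry.effect_allele.upper(), ry.other_allele.upper()

    if rx.palindromic:
        if _palindrome_ambiguous(rx.eaf, window) or _palindrome_ambiguous(ry.eaf, window):
            dropped[rx.snp_id] = "palindrome_ambiguous"
            return None
        # for a palindrome the swapped pair equals the complemented pair,
        # so string matching fixes allele labels and eaf fixes the strand
        if (ea2, oa2) == (ea, oa):
            aligned = ry
        elif (ea2, oa2) == (oa, ea):
            aligned = ry.flipped()
        else:
            dropped[rx.snp_id] = "allele_mismatch"
            return None
        if (rx.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
            aligned = aligned.flipped()  # opposite strands reported
        return aligned

    if (ea2, oa2) == (ea, oa):
        return ry
    if (ea2, oa2) == (oa, ea):
        return ry.flipped()
    cea2, coa2 = complement(ea2), complement(oa2)
    if (cea2, coa2) == (ea, oa):
        return ry
    if (cea2, coa2) == (oa, ea):
        return ry.flipped()
    dropped[rx.snp_id] = "allele_mismatch"
    return None


def _palindrome_ambiguous(eaf: float | None, window: float) -> bool:
    if eaf is None:
        return True
    return eaf == 0.5 or abs(eaf - 0.5) < window
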