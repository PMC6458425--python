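"""Allele harmonization for two-sample MR.

Exposure and outcome summary statistics typically come from different
GWAS, which may report effects for opposite alleles or on opposite DNA
strands.  Before any causal estimate is computed, every instrument must
refer to the same effect allele in both studies, and by convention the
instruments are oriented so the exposure-increasing allele is counted
(beta_exp > 0).

Palindromic variants (A/T or G/C) are strand-ambiguous: the allele
labels alone cannot reveal whether the two studies are on the same
strand.  They are resolved by allele frequency when the frequency is
informative (minor allele matching outside a configurable ambiguity
window around 0.5), dropped when it is not, or taken at face value,
depending on policy.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["harmonize", "AMBIGUITY_WINDOW"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window within which a palindromic SNP's strand cannot be inferred
AMBIGUITY_WINDOW = (0.42, 0.58)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_policy: str = "infer_by_eaf",
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele and orient
    instruments to the exposure-increasing allele.

    Parameters
    ----------
    exposure, outcome
        Summary-statistic tables in the standard dialect
        (``snp, effect_allele, other_allele, eaf, beta, se, ...``),
        matched on ``snp``.
    palindromic_policy
        ``drop_ambiguous`` excludes palindromic SNPs whose eaf (either
        study) falls inside the ambiguity window; ``infer_by_eaf``
        additionally aligns unambiguous palindromes by minor-allele
        matching; ``keep`` trusts the labels as printed.

    Returns
    -------
    DataFrame with columns ``snp, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out, aligned_allele, other_allele, flags`` — one row per
    retained instrument, ``beta_exp > 0`` throughout.  Excluded records
    are reported in the ``.attrs['exclusions']`` dict (snp → reason).
    """
    if palindromic_policy not in ("drop_ambiguous", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")

    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    exclusions: dict[str, str] = {}
    for snp in exp.index.difference(out.index):
        exclusions[snp] = "missing in outcome study"
    for snp in out.index.difference(exp.index):
        exclusions[snp] = "missing in exposure study"

    rows = []
    for snp in exp.index.intersection(out.index):
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = str(e.effect_allele), str(e.other_allele)
        ea_o, oa_o = str(o.effect_allele), str(o.other_allele)
        flags: list[str] = []

        beta_out = float(o.beta)
        eaf_out = float(o.eaf)
        palindromic = _is_palindromic(ea_e, oa_e)

        if palindromic:
            # labels identical to their own complements: only frequency
            # can tell whether the studies share a strand
            if {ea_o, oa_o} != {ea_e, oa_e}:
                exclusions[snp] = f"incompatible alleles {ea_e}/{oa_e} vs {ea_o}/{oa_o}"
                continue
            if palindromic_policy in ("drop_ambiguous", "infer_by_eaf"):
                lo, hi = AMBIGUITY_WINDOW
                if (lo <= float(e.eaf) <= hi) or (lo <= eaf_out <= hi):
                    exclusions[snp] = "excluded_palindromic: frequency ambiguous"
                    continue
                # minor-allele matching: for a palindrome the printed labels
                # carry no strand information at all — the effect alleles
                # refer to the same physical allele iff their frequencies
                # fall on the same minor/major side
                same_side = (float(e.eaf) < 0.5) == (eaf_out < 0.5)
                if not same_side:
                    beta_out = -beta_out
                    eaf_out = 1 - eaf_out
                    flags.append("flipped")
                flags.append("palindromic_resolved")
            else:  # keep: face value
                if ea_o == oa_e:
                    beta_out = -beta_out
                    eaf_out = 1 - eaf_out
                    flags.append("flipped")
        else:
            if {ea_o, oa_o} == {ea_e, oa_e}:
                swapped = ea_o == oa_e
            elif {ea_o, oa_o} == {_COMPLEMENT[ea_e], _COMPLEMENT[oa_e]}:
                # other strand: complement outcome labels, then compare
                ea_o, oa_o = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
                swapped = ea_o == oa_e
                flags.append("strand_complemented")
            else:
                exclusions[snp] = f"incompatible alleles {ea_e}/{oa_e} vs {ea_o}/{oa_o}"
                continue
            if swapped:
                beta_out = -beta_out
                eaf_out = 1 - eaf_out
                flags.append("flipped")

        beta_exp = float(e.beta)
        eaf_exp = float(e.eaf)
        aligned, other = ea_e, oa_e
        if beta_exp < 0:
            # orient to the exposure-increasing allele
            beta_exp, beta_out = -beta_exp, -beta_out
            eaf_exp, eaf_out = 1 - eaf_exp, 1 - eaf_out
            aligned, other = oa_e, ea_e

        rows.append(
            {
                "snp": snp,
                "beta_exp": beta_exp,
                "se_exp": float(e.se),
                "beta_out": beta_out,
                "se_out": float(o.se),
                "eaf_exp": eaf_exp,
                "eaf_out": eaf_out,
                "aligned_allele": aligned,
                "other_allele": other,
                "flags": ";".join(flags),
            }
        )

    result = pd.DataFrame(
        rows,
        columns=[
            "snp", "beta_exp", "se_exp", "beta_out", "se_out",
            "eaf_exp", "eaf_out", "aligned_allele", "other_allele", "flags",
        ],
    )
    # preserve the exposure table's instrument order
    if len(result):
        order = {s: i for i, s in enumerate(exposure["snp"])}
        result = result.sort_values("snp", key=lambda s: s.map(order)).reset_index(drop=True)
    result.attrs["exclusions"] = exclusions
    return result
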