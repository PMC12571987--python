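"""Built-in worked example: a published gut-microbiota -> inflammatory
cytokine -> brain-structural-connectivity mediation screen.

The table lists, for 23 significant mediation triples, the IVW total
effect (taxon -> connectivity), direct effect A (taxon -> cytokine),
direct effect B (cytokine -> connectivity), the delta-method mediation
effect, and the mediated proportion, as printed (effects to 3 decimals,
proportions to 2).  It serves as the reference fixture for the
product-of-coefficients arithmetic: A x B must reproduce the printed
mediation effect at its printed rounding.

Outcome names abbreviate white-matter structural connectivity between
brain networks/structures: e.g. "LH-CN->accumbens" is left-hemisphere
control network to accumbens.
"""

from __future__ import annotations

import io

import pandas as pd

_MEDIATION_TSV = """\
exposure\tmediator\toutcome\ttotal_effect\tdirect_a\tdirect_b\tmediation_effect\tproportion_pct
family_Lactobacillaceae\tG-CSF\tLH-CN->accumbens\t0.065\t0.134\t0.062\t0.008\t12.78
genus_Lachnospiraceae_UCG010\tG-CSF\tLH-CN->accumbens\t0.102\t0.21\t0.062\t0.013\t12.63
genus_Desulfovibrio\tG-CSF\tLH-CN->accumbens\t-0.122\t-0.264\t0.062\t-0.016\t13.36
family_Victivallaceae\tHGF\tLH-LN->LH-DMN\t-0.042\t0.096\t-0.105\t-0.01\t23.83
genus_Blautia\tHGF\tRH-SMN->RH-LN\t-0.397\t0.538\t-0.07\t-0.038\t9.54
family_Clostridiales_vadin_BB60\tIL-13\tRH-SMN->RH-DMN\t-0.076\t-0.221\t0.033\t-0.007\t9.58
genus_Paraprevotella\tIL-13\tLH-SMN->LH-DMN\t0.06\t0.184\t0.033\t0.006\t10.09
genus_Phascolarctobacterium\tIL-13\tLH-SVAN->caudate\t0.098\t0.264\t0.036\t0.01\t9.74
genus_Oxalobacter\tIL-18\tLH-VN->thalamus\t-0.047\t-0.187\t0.037\t-0.007\t14.51
genus_Ruminiclostridium6\tIP-10\tRH-SMN->amygdala\t-0.066\t-0.231\t0.055\t-0.013\t19.17
genus_Sellimonas\tIP-10\tRH-DMN->accumbens\t0.07\t0.184\t0.051\t0.009\t13.41
genus_Ruminococcaceae_UCG005\tPDGF-BB\tLH-LN->RH-DAN\t0.070\t-0.165\t-0.063\t0.010\t14.73
genus_Sellimonas\tMIG\tRH-SMN->accumbens\t0.048\t0.147\t0.051\t0.008\t15.55
genus_Ruminococcaceae_UCG002\tMIG\tLH-VN->putamen\t0.065\t0.243\t0.044\t0.011\t16.40
family_Defluviitaleaceae\tRANTES\tRH-SVAN->RH-CN\t-0.072\t-0.265\t0.051\t-0.013\t18.65
family_Rhodospirillaceae\tRANTES\tLH-VN->RH-DAN\t-0.074\t-0.21\t0.058\t-0.012\t16.68
genus_Lachnospiraceae_NK4A136\tRANTES\tLH-DMN->RH-VN\t-0.084\t-0.191\t0.065\t-0.012\t14.67
genus_Eubacterium_xylanophilum\tRANTES\tLH-SMN->LH-DMN\t-0.112\t-0.351\t0.05\t-0.017\t15.6
genus_Lachnospiraceae_NK4A136\tRANTES\tLH-SVAN->RH-VN\t-0.068\t-0.191\t0.108\t-0.021\t30.18
genus_Lachnospiraceae_NK4A136\tRANTES\tLH-SMN->RH-DMN\t-0.086\t-0.191\t0.062\t-0.012\t13.79
genus_Lachnospiraceae_NK4A136\tRANTES\tLH-SVAN->RH-CN\t-0.062\t-0.191\t0.06\t-0.011\t18.46
genus_Ruminococcaceae_UCG003\tTNF-B\tRH-SMN->caudate\t-0.116\t-0.461\t0.04\t-0.018\t15.66
family_Victivallaceae\tTRAIL\tRH-LN->amygdala\t0.052\t0.095\t0.04\t0.004\t7.34
"""


def load_mediation_examples() -> pd.DataFrame:
    """The 23-row published mediation screen used as a worked example."""
    return pd.read_csv(io.StringIO(_MEDIATION_TSV), sep="\t")
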