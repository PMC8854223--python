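"""Generate a synthetic spontaneous-speech corpus and inspect its collinearity.

The generator produces a Zipfian lexicon, lays tokens out in pause-delimited
speech epochs, and the parameter table then shows the documented sign
structure: ease of articulation rises with frequency, syllable count falls
with frequency, and longer words last longer and come later in their epoch.
"""

from neurolex import DiscourseConfig, generate_discourse, generate_lexicon
from neurolex.neurocorr import parameter_correlation_matrix
from neurolex.pipeline import parameter_table

lexicon = generate_lexicon(1200, zipf_exponent=1.0, seed=42)
discourse = generate_discourse(lexicon, DiscourseConfig(seed=42))
print(
    f"{len(discourse.tokens)} tokens in {len(discourse.epochs)} speech epochs "
    f"({len(discourse.clauses)} clauses)"
)

table = parameter_table(discourse)  # content words, log-transformed
corr = parameter_correlation_matrix(table)

print("\nPearson r between the linguistic parameters (S = strong, |r| > 0.4):")
cols = list(table.columns)
print("        " + "".join(f"{c:>8}" for c in cols))
for a in cols:
    row = []
    for b in cols:
        if a == b:
            row.append(f"{'-':>8}")
        else:
            tag = "S" if corr.strong.loc[a, b] else " "
            row.append(f"{corr.r.loc[a, b]:>7.2f}{tag}")
    print(f"{a:>8}" + "".join(row))

# Expected signs: EoA-FRQ positive, EoA-NoS negative, FRQ-NoS negative,
# CVR-NoS negative, NoS-ws_we strongly positive.  This collinearity is why
# the neurocorrelation analysis needs residualization.
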