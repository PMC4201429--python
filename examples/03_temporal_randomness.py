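"""Serial runs test: is the index series random over time?

Runs the full pipeline (overall assemblage, all three temporal scales) on a
neutral campaign and prints the runs-test table. Under neutral assembly the
chronological NRI/NTI series should usually be indistinguishable from serial
randomness; runs of persistent clustering or overdispersion would show up as
too few runs (small p).
"""

import tempophylo as tp
from tempophylo.null_models import NullConfig

phylo, guilds, records = tp.default_fixture(seed=1)
config = tp.AnalysisConfig(groups=("overall",),
                           null=NullConfig(n_rand=999, seed=3), seed=5)
result = tp.run_analysis(phylo, records, guilds, config)

cols = ["scale", "index", "n_plus", "n_minus", "runs", "method", "p_value", "decision"]
print(result.runs_table[cols].to_string(index=False))

# n_plus / n_minus count units above/below the SES null center (zero); `runs`
# is the number of maximal same-sign blocks in chronological order. Small p
# means the series departs from serial randomness (too few runs =
# persistence, too many = alternation).
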