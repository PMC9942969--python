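"""Population rates from the packaged observed pairing table.

The packaged fixture encodes the published pairing table for 20 black
duck maternal lineages from coastal North Carolina (19 sampled nests
plus one clutch laid by an unsampled parasitizing female).  No genotype
data is needed: the rates are pure counting.
"""

import json

from nestkin.strategies import (load_reference_pairing_table,
                                rates_from_pairing_table)

pt = load_reference_pairing_table()
rates = rates_from_pairing_table(pt)
print(json.dumps(rates, indent=1))
# 7 of 19 nests (37%) were multi-paternal through extra-pair copulation;
# 13 of 20 maternal lineages (65%) were monogamous; 24 paternal lineages
# explain the 80 sampled offspring; 16 of 19 sampled hens were pure
# black duck.
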