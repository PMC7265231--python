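"""Published headline cell counts used as worked examples.

These are the per-condition cell totals and podocyte counts from a published
mouse kidney dissociation-protocol comparison (cold-active protease on ice
vs. enzymatic digestion at 37 °C, 10x Chromium scRNA-seq, pooled biological
triplicates).  They serve as a tiny real-data fixture for the composition
chi-square test: the percentages and significance flag are recomputed from
these raw counts, never stored.
"""

from __future__ import annotations

#: Total high-quality cells per dissociation condition (pooled replicates).
FRESH_CELL_COUNTS: dict[str, int] = {"cold": 11_851, "warm": 11_257}

#: Podocytes detected per condition within the totals above.
PODOCYTE_COUNTS: dict[str, int] = {"cold": 330, "warm": 3}
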