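"""Brute-force oracles for the test suite (independent of the checked paths)."""

from phemr.validation import (  # noqa: F401
    enumerate_tree_marginals,
    meta_analysis_of_ratios,
    random_grid,
    random_tree,
)
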