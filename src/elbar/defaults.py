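"""Central registry of default parameters, echoed into every run report."""

DEFAULTS = {
    "nbins": 20,
    "min_per_bin": 100,
    "tau": 0.1,
    "q_low_level": 0.05,
    "q_high_level": 0.95,
    "threshold": 0.05,
    "mode": "ecdf",
    "include_oob": False,
    "include_controls": True,
    "oob_in_binning": True,
    "pool_beta_window": True,
}
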