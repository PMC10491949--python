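"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input file or run configuration is malformed or incomplete.

    Raised before any computation starts, e.g. when a required column is
    missing from a catalog or MetaboAnalyst export, or when a run config
    references files that do not exist.
    """
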