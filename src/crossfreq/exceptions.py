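"""Exception hierarchy used across the package.

Every error raised by crossfreq derives from :class:`CrossfreqError`, so
batch drivers and the CLI can distinguish our failures from genuine bugs.
"""


class CrossfreqError(Exception):
    """Base class for all crossfreq errors."""


class InvalidBandError(CrossfreqError):
    """A band-pass specification has an edge outside (0, Nyquist)."""


class TrimError(CrossfreqError):
    """A trial is too short for the requested edge trimming."""


class DegenerateInputError(CrossfreqError):
    """An input (all-zero or constant series) makes the quantity undefined."""


class EmptyBinError(CrossfreqError):
    """A phase bin received no samples; the mean amplitude is undefined there.

    Carries the offending bin index as ``bin_index``.
    """

    def __init__(self, bin_index: int, n_bins: int):
        self.bin_index = int(bin_index)
        self.n_bins = int(n_bins)
        super().__init__(
            f"phase bin {bin_index} of {n_bins} received no samples; "
            "use longer trials or fewer bins"
        )


class ConfigError(CrossfreqError):
    """A run configuration is malformed (unknown key, bad value)."""


class ParseError(CrossfreqError):
    """A trial/grid file is malformed or missing required metadata."""
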