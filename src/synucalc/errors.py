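"""Shared exception types."""


class InputError(ValueError):
    """Invalid or inconsistent user input (wrong residues, empty tables...)."""


class FitError(RuntimeError):
    """A model fit failed to converge or had no signal to fit."""


class NoTransitionError(FitError):
    """A kinetic trace shows no detectable growth transition."""
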