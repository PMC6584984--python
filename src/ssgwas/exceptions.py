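"""Exception hierarchy; the CLI maps these onto exit codes (2 input, 3 numerical)."""


class SSGwasError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SSGwasError):
    """Malformed or inconsistent user input (files, IDs, configuration)."""


class NumericalError(SSGwasError):
    """Numerical failure: singular matrices, non-positive-definite systems, etc."""
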