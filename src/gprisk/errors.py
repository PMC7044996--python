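"""Exception hierarchy for the gprisk pipeline."""


class GPRiskError(Exception):
    """Base class for all gprisk errors."""


class ConfigurationError(GPRiskError):
    """A configuration value is invalid; the message names the field."""


class DataError(GPRiskError):
    """Input data violate a contract (unknown codes, mismatched ids...)."""


class SchemaError(GPRiskError):
    """Tables do not align on the expected cells or columns."""


class ContractError(GPRiskError):
    """An operation was called out of order or on ineligible rows."""


class FitError(GPRiskError):
    """A model fit failed; carries optimiser diagnostics in the message."""
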