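"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input tables (CLI exit code 1);
``ConfigError`` covers bad configuration such as unknown scenario names or
non-positive monetarization inputs (CLI exit code 2).
"""


class FoodCostError(Exception):
    """Base class for all package errors."""


class DataError(FoodCostError):
    """Input tables are malformed, inconsistent, or missing required rows."""


class ConfigError(FoodCostError):
    """Configuration values are invalid or refer to unknown entities."""
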