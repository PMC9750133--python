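"""Exception hierarchy shared across the pipeline.

Configuration errors (bad parameters, malformed requests) exit with code 2
from the CLI; data errors (inputs inconsistent with their declared meaning,
e.g. a known editing site that is not a C) exit with code 3.
"""


class OrganeditError(Exception):
    exit_code = 1


class ConfigurationError(OrganeditError):
    exit_code = 2


class DataError(OrganeditError):
    exit_code = 3
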