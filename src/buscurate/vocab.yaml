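# Field-matching vocabulary: one list of regular expressions per field.
# Patterns run against uppercased, whitespace-normalised OCR strings.
# Extend or replace per dataset; pass a custom file via
# `load_vocabulary(path)` or the CLI's --vocab option.
#
# Quadrant-style location notation (LOQ, RIQ, ...) is deliberately absent:
# only clock-face notation is recognised, matching ACR BI-RADS guidance.

laterality_left:
  - '\bLEFT\b'
  - '\bLT\b'
  - '\bL(?=\s+(?:BREAST|AX\w*))'
laterality_right:
  - '\bRIGHT\b'
  - '\bRT\b'
  - '\bR(?=\s+(?:BREAST|AX\w*))'

# Transducer orientation aliases map onto the canonical labels below.
orientation_RAD:
  - '\bRAD\b'
orientation_ARAD:
  - '\bARAD\b'
  - '\bANTI-?RAD\b'
orientation_TRANS:
  - '\bTRANS\b'
  - '\bTRV\b'
orientation_LONG:
  - '\bLONG\b'
orientation_SAG:
  - '\bSAG\b'
orientation_OBL:
  - '\bOBL\b'

# Clock-face anatomic location: H:MM with hour 1-12, or "H O'CLOCK".
clock_position:
  - '\b(1[0-2]|[1-9]):([0-5][0-9])\b'
  - "\\b(1[0-2]|[1-9])\\s*O'?CLOCK\\b"

# Distance from the nipple in centimeters: a number adjacent to CM plus a
# from-nipple marker (FN / CMFN / FROM NIPPLE).
distance_from_nipple:
  - '\b(\d+(?:\.\d+)?)\s*CM\s*(?:FN\b|FROM\s+NIPPLE\b)'

axilla:
  - '\bAXILLA\b'
  - '\bAXILLARY\b'
  - '\bAX\b'

# Lesion measurements: number-CM groups NOT claimed by the distance field;
# "A X B CM" yields both numbers.
measurement:
  - '\b(\d+(?:\.\d+)?)(?:\s*X\s*(\d+(?:\.\d+)?))?\s*CM\b(?!\s*(?:FN\b|FROM\s+NIPPLE\b))'

procedural:
  - '\bBIOPSY\b'
  - '\bBX\b'
  - '\bFNA\b'
  - '\bASPIRATION\b'
  - '\bCYST\s+ASP\b'
  - '\bCLIP\b'
  - '\bMARKER\b'
  - '\bCOIL\b'
  - '\bWIRE\b'
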