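"""Parse verbatim collection-date strings at mixed precision.

Type-series metadata rarely report exact days: a date may be a range
("5–7 December 2008"), a month, or just a year.  Each string resolves to
the midpoint of the interval it implies (floor of the mean day), with the
precision class preserved.
"""

from taxalag import parse_date_text

for raw in ["12 March 2010", "5–7 December 2008", "February 2007",
            "1925", "28 February – 3 March 2008"]:
    cd = parse_date_text(raw)
    print(f"{raw:32s} -> {cd.resolved}  precision={cd.precision.value:10s}"
          f" span={cd.span_days:3d} d")

# The resolved date is what enters lag computation and trip segmentation;
# span_days is the size of the dating uncertainty (0 = exact day).
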