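"""How long can a logger record before its memory fills?

Fill time = (memory - header) / (samples_per_s x axes).  Capacity is in
sample slots; the default ~65,000-slot logger recording 3 axes every 30 s
lasts about a week, while 1-Hz recording fills it in hours.
"""

from calanfeed import LoggerSpec, fill_time

for label, spec in [
    ("3 axes @ 1/30 s (default)", LoggerSpec()),
    ("3 axes @ 1/10 s", LoggerSpec(samples_per_s=0.1)),
    ("1 axis  @ 1/30 s", LoggerSpec(n_axes=1)),
    ("3 axes @ 1 Hz", LoggerSpec(samples_per_s=1.0)),
]:
    ft = fill_time(spec)
    print(f"{label:28s} -> {ft.seconds:>10,.0f} s = {ft.days:5.1f} d")
print("pick the coarsest epoch that still resolves the shortest bout of interest;"
      " 30 s is ~1.5% of a ~30-min intermeal criterion")
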