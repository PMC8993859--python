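"""Ingesting check-in files, edge lists, and call records from disk.

Writes tiny files in the supported dialects, reads them back, applies the
activity filter, and summarizes basic mobility statistics.
"""

import tempfile
from pathlib import Path

from mobinfo import (
    filter_dataset,
    read_cdr,
    read_checkins,
    read_social_edges,
    summarize_mobility,
)

tmp = Path(tempfile.mkdtemp())

# check-in TSV: user, ISO-8601 time, latitude, longitude, location id
checkins = tmp / "checkins.tsv"
rows = []
for i in range(6):
    rows.append(f"alice\t2010-04-01T{8 + i:02d}:00:00Z\t40.{i}\t-75.0\tcafe_{i % 2}")
for i in range(3):
    rows.append(f"bob\t2010-04-01T{9 + i:02d}:30:00Z\t40.0\t-75.{i}\tpark")
rows.append("carol\t2010-04-01T12:00:00Z\t41.0\t-74.0\t")  # missing location: dropped
checkins.write_text("\n".join(rows) + "\n")

ds, report = read_checkins(checkins)
print(f"read {report.rows_read} rows, dropped {report.rows_dropped}, "
      f"found {report.users_found} users")

edges_file = tmp / "edges.tsv"
edges_file.write_text("alice\tbob\nbob\talice\n")  # duplicates collapse
ds.social_edges = read_social_edges(edges_file)
print(f"social edges: {sorted(ds.social_edges)}")

filtered = filter_dataset(ds, min_checkins=4)
print(f"users with >= 4 check-ins: {filtered.users}")

summary = summarize_mobility(ds)
for uid in ds.users:
    jumps = summary.jump_lengths_km.get(uid)
    rg = summary.radius_of_gyration_km.get(uid)
    print(f"  {uid}: {summary.distinct_locations[uid]} distinct locations, "
          f"radius of gyration {rg:.1f} km, {len(jumps)} jumps")

# call-record CSV: caller, callee, epoch seconds, antenna
cdr = tmp / "calls.csv"
cdr.write_text("u1,u2,1000,antA\nu2,u1,2000,antA\nu1,u3,3000,antB\n")
cds, creport = read_cdr(cdr)
print(f"CDR: {creport.rows_read} calls -> caller trajectories "
      f"{ {u: list(t.locations) for u, t in cds.trajectories.items()} }")
print()
print("Each call places the caller at an antenna; the full call log is kept")
print("so social ties can be inferred from reciprocal calling.")
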