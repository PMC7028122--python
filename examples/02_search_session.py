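"""One run of the visual-search test for a simulated observer.

Builds the 7 x 9 grid of a 26 cm x 17.3 cm screen viewed from 50 cm,
schedules all 62 non-centre target locations in seeded random order, draws
a response time at each location from the observer's eccentricity power
law, and summarises the run by its median RT.
"""

import numpy as np

from tabvis import ObserverModel, SearchGrid, run_search_session, rt_mean

grid = SearchGrid()
observer = ObserverModel()  # field-fit RT power law: -13.14 * ecc**-0.05 + 13.56

print(f"grid: {grid.n_cols} cols x {grid.n_rows} rows = {grid.n_cells} cells, "
      f"centre cell (Reference) at location {grid.center_location}")
print(f"eccentricity range of targets: "
      f"{min(grid.eccentricity(l) for l in grid.target_locations):.2f} - "
      f"{max(grid.eccentricity(l) for l in grid.target_locations):.2f} deg")
for ecc in (3.0, 8.0, 15.0):
    print(f"  mean RT at {ecc:4.1f} deg: {rt_mean(ecc, observer):.2f} s")

result = run_search_session(observer, grid, subset="all", seed=11)
print(f"\nsession: {len(result.trials)} trials, median RT {result.median_rt:.2f} s")

inner = [rt for loc, rt in result.trials if grid.eccentricity(loc) < 6]
outer = [rt for loc, rt in result.trials if grid.eccentricity(loc) >= 10]
print(f"median RT, targets < 6 deg: {np.median(inner):.2f} s; "
      f">= 10 deg: {np.median(outer):.2f} s")
print("Peripheral targets take longer to find; the median RT over all")
print("locations is the test's summary score (larger = poorer search).")
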