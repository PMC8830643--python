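startYear: 1860
endYear: 2050
initialCouples: 200
townRows: 8
townCols: 8
densityWeights:
- - 0.007411594340475331
  - 0.009300333586172056
  - 0.011052944877436417
  - 0.01215840042213236
  - 0.01215840042213236
  - 0.011052944877436417
  - 0.009300333586172056
  - 0.007411594340475331
- - 0.009300333586172056
  - 0.01215840042213236
  - 0.015105223469443943
  - 0.017169400793614963
  - 0.017169400793614963
  - 0.015105223469443943
  - 0.01215840042213236
  - 0.009300333586172056
- - 0.011052944877436417
  - 0.015105223469443943
  - 0.01994533079308112
  - 0.024096307191797034
  - 0.024096307191797034
  - 0.01994533079308112
  - 0.015105223469443943
  - 0.011052944877436417
- - 0.01215840042213236
  - 0.017169400793614963
  - 0.024096307191797034
  - 0.03271945376311765
  - 0.03271945376311765
  - 0.024096307191797034
  - 0.017169400793614963
  - 0.01215840042213236
- - 0.01215840042213236
  - 0.017169400793614963
  - 0.024096307191797034
  - 0.03271945376311765
  - 0.03271945376311765
  - 0.024096307191797034
  - 0.017169400793614963
  - 0.01215840042213236
- - 0.011052944877436417
  - 0.015105223469443943
  - 0.01994533079308112
  - 0.024096307191797034
  - 0.024096307191797034
  - 0.01994533079308112
  - 0.015105223469443943
  - 0.011052944877436417
- - 0.009300333586172056
  - 0.01215840042213236
  - 0.015105223469443943
  - 0.017169400793614963
  - 0.017169400793614963
  - 0.015105223469443943
  - 0.01215840042213236
  - 0.009300333586172056
- - 0.007411594340475331
  - 0.009300333586172056
  - 0.011052944877436417
  - 0.01215840042213236
  - 0.01215840042213236
  - 0.011052944877436417
  - 0.009300333586172056
  - 0.007411594340475331
makehamA: 0.0001
gompertzB: 8.0e-06
gompertzC: 0.095
birthProb: 0.13
fertileAgeMin: 17
fertileAgeMax: 42
partnerFormProb: 0.12
partnerDissolveProb: 0.015
leaveHomeProb: 0.3
householdMigrationProb: 0.04
employmentEntryProb: 0.75
jobLossProb: 0.05
reemploymentProb: 0.35
careNeedHours:
- 0.0
- 8.0
- 16.0
- 30.0
- 80.0
kinProvisionScaleSameTown: 400.0
kinProvisionScaleOtherTown: 80.0
outOfHouseholdCapacityFactor: 0.5
pricePerHour: 16.7
seed: 0
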