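TY  - JOUR
ID  - p01
TI  - Recruitment of Amphiprion percula on degraded coral reefs
AB  - We monitored settlement of Amphiprion percula across reef sites. Density declined with disturbance on the coral reef studied.
KW  - reef fish
KW  - recruitment
PY  - 1998
ER  -
TY  - JOUR
ID  - p02
TI  - Seasonal growth in temperate seagrass beds
AB  - Growth of Zostera marina was measured in seagrass beds over two seasons. Biomass peaked in summer.
KW  - seagrass
PY  - 2003
ER  -
TY  - JOUR
ID  - p03
TI  - Canopy dynamics of Macrocystis pyrifera in kelp forests
AB  - Kelp forests dominated by Macrocystis pyrifera show strong seasonal variation in canopy cover.
KW  - kelp
PY  - 2007
ER  -
TY  - JOUR
ID  - p04
TI  - Gastropod harvesting in mangrove forests
AB  - Strombus gigas was collected near mangrove forests by artisanal fishers. Catch rates varied among sites.
PY  - 1995
ER  -
TY  - JOUR
ID  - p05
TI  - Damselfish territories on a coral-reef flat
AB  - Chromis viridis and Chromis atripectoralis defended adjacent territories. Aggression increased with density.
PY  - 2001
ER  -
TY  - JOUR
ID  - p06
TI  - Coral recruitment after bleaching
AB  - Recruitment of Anthias perculus was quantified after a bleaching event. No ecosystem phrase appears in this record.
PY  - 1999
ER  -
TY  - JOUR
ID  - p07
TI  - A record with no publication year
AB  - This malformed entry mentions Zostera marina in seagrass beds but lacks a year tag.
ER  -
TY  - JOUR
ID  - p08
TI  - Gastropoda assemblages of seagrass meadows
AB  - Community structure of Gastropoda was surveyed across seagrass meadows at five sites.
PY  - 2008
ER  -
TY  - JOUR
ID  - p09
TI  - Long term monitoring design
AB  - A sampling design for anemonefish of the genus Amphiprion is described.
KW  - coral reefs
KW  - monitoring
PY  - 1988
ER  -
TY  - JOUR
ID  - p10
TI  - Biodiversity of Animalia in a kelp forest
AB  - Only a kingdom level name appears here, in a kelp forest context.
PY  - 2005
ER  -
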