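key,full_name,low_anchor,high_anchor
habitat,Habitat specificity,Habitat generalist using very common habitats during the entire ontogeny,Specialist on an abundant habitat
prey,Prey specificity,Eats a large variety of prey (opportunistic feeder),Partial to a single prey type (prey specialist)
mobility,Adult mobility,Highly mobile and non-site dependent adults,Site dependent adults with limited mobility
dispersal,Dispersal of early life stages,High egg and larvae dispersal,Low egg and larval dispersal
ELH,Early life history survival and settlement requirements,Eggs and larvae have minimal requirements,Eggs and larvae have some specific requirements
complexity,Complexity in reproductive strategy,Simple reproductive strategy (no more than one characteristic),Complex reproductive strategy (three characteristics)
spawning,Population spawning cycle,Consistent spawning throughout the year without a defined season,One spawning event per year within a confined time frame
temperature,Sensitivity to temperature,Wide temperature range throughout ontogeny and adapted to warmer water,Limited temperature range and adapted to colder water
salinity,Sensitivity to salinity,Euryhaline life stages,Limited salinity range
acidification,Sensitivity to ocean acidification,Does not rely on pH sensitive taxa or shows no effect of acidification,Reliant on sensitive taxa or life stages negatively affected by decreased pH
growth,Population growth rate,High population growth rate and high productivity,Low growth rate and low productivity
other,Additional stressors,Limited stress (no more than one known stressor),Moderate to high stress (two to three known stressors)
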