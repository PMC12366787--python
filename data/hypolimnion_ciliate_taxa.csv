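name,class_name,feeding_mode,uptake_mean,uptake_sd,proportion_pct
Scuticociliate undescribed,Oligohymenophorea,bacterivorous,202,103,81.8
Vorticella sp.,Oligohymenophorea,bacterivorous,775,88,0.3
Halteria sp.,Spirotrichea,omnivorous,324,71,3.4
Rimostrombidium brachykinetum,Spirotrichea,omnivorous,43,36,2.4
Mesodinium sp.,Litostomatea,predatory,,,6.0
Actinobolina smalli,Litostomatea,predatory,,,0.02
Urotricha globosa,Prostomatea,algivorous,,,4.8
Balanion planctonicum,Prostomatea,algivorous,,,0.1
Coleps hirtus,Prostomatea,detritivorous,,,0.2
Stokesia vernalis,Oligohymenophorea,algivorous,,,0.3
Cinetochilum margritaceum,Oligohymenophorea,detritivorous,,,0.2
Astylozoon fallax,Oligohymenophorea,detritivorous,,,0.1
Cyrtolophosis mucicola,Colpodea,detritivorous,,,0.1
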