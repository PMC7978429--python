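(Crocodylus_johnstoni:245,(Marasuchus_lilloensis:5,(Lesothosaurus_diagnosticus:36,(Plateosaurus_engelhardti:23,(Coelophysis_bauri:15,(Dilophosaurus_wetherilli:7,(Allosaurus_fragilis:30,(Tyrannosaurus_rex:99,((Deinonychus_antirrhopus:35,Velociraptor_mongoliensis:73)Dromaeosauridae:15,(Archaeopteryx_lithographica:5,(Gallus_gallus:40,Phasianus_colchicus:40)Phasianidae:115)Avialae:5)Eumaniraptora:5)Coelurosauria:15)Avetheropoda:20)Averostra:25)Neotheropoda:8)Saurischia:2)Dinosauria:5)Dinosauromorpha:5)Archosauria;
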