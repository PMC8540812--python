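# Published trap-system parameter sets: catch probability next to the trap
# (sptfer0), half-catch distance d50 (m, with SEM) and collection radius
# rmax (m). rmax_estimated=1 marks collection radii that were estimated
# indirectly (Miller-et-al. method) rather than measured.
key,label,trap_type,sptfer0,d50_m,d50_sem_m,rmax_m,rmax_estimated
l_dispar,L. dispar,Pheromone,0.37,27.3,3,1600,0
codling_moth,Codling moth (C. pomonella),Pheromone,0.7,6.5,1,260,1
h_halys,Brown marmorated stink bug (H. halys),Pheromone,0.5,7,0.9,130,1
pine_sawfly,European pine sawfly (N. sertifer),Pheromone,0.09,250,21,1040,0
d_suzukii,Spotted wing drosophila (D. suzukii),Chemical,0.02,27.7,7,90,1
corn_rootworm,Western corn rootworm (D. virgifera),Pheromone,0.09,11,0.4,60,1
d_frontalis,Southern pine beetle (D. frontalis),Pheromone,0.08,23,2.8,1000,0
d_pseudotsugae,Douglas fir beetle (D. pseudotsugae),Pheromone,0.07,184,33,600,0
erebidae,Erebidae assemblage,Light,0.52,10.6,1.4,40,0
sphingidae,Sphingidae assemblage,Light,0.31,91.6,8,175,1
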